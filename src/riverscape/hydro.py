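"""Raster hydrology: depression filling, D8 routing, flow accumulation.

The standard single-flow-direction toolchain that turns a projected DEM into
the quantities the stream delineation thresholds: every valid cell is routed
to exactly one of its eight neighbours (or off-grid), and contributing area
is the count of cells draining through a cell times the cell area.

Conventions (fixed for cross-platform determinism):

* Neighbour order is clockwise starting at East:
  E, SE, S, SW, W, NW, N, NE. Ties in steepest descent are broken by this
  order. Diagonal flow distance is ``cell_size * sqrt(2)``.
* Depressions are filled by boundary-seeded priority-flood (epsilon-free);
  flats left at the fill level are resolved by a breadth-first pass that
  drains each flat toward its spill cell.
* Valid cells on the grid edge, or adjacent to nodata, with no downhill
  in-grid neighbour drain off-grid and are coded OUTLET.
* Accumulation counts include the cell itself, so contributing area in km^2
  is directly ``count * cell_area`` and a headwater rule like "catchment of
  at least 2 km^2" thresholds it with no off-by-one.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .grid import ElevationGrid

__all__ = [
    "OUTLET",
    "NODATA_DIR",
    "D8_OFFSETS",
    "D8FlowField",
    "AccumulationGrid",
    "fill_depressions",
    "d8_flow_direction",
    "flow_accumulation",
    "delineate_streams",
    "catchment_mask",
    "upstream_accumulate",
]

# clockwise from East: E, SE, S, SW, W, NW, N, NE
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])

OUTLET = -1
NODATA_DIR = -2


class FlatResolutionError(RuntimeError):
    """A flat region could not be drained to any lower terrain."""


@dataclass
class D8FlowField:
    """Per-cell D8 pointer field.

    ``direction[r, c]`` is the index into :data:`D8_OFFSETS` of the receiving
    neighbour, or :data:`OUTLET` (drains off-grid / into nodata) or
    :data:`NODATA_DIR` (invalid cell).
    """

    direction: np.ndarray
    cell_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.direction.shape

    @property
    def valid(self) -> np.ndarray:
        return self.direction != NODATA_DIR

    def receiver(self, row: int, col: int) -> tuple[int, int] | None:
        """(row, col) of the cell this cell drains to, None for outlets."""
        d = self.direction[row, col]
        if d == NODATA_DIR:
            raise ValueError(f"cell ({row}, {col}) is nodata")
        if d == OUTLET:
            return None
        dr, dc = D8_OFFSETS[d]
        return row + dr, col + dc

    def step_length_m(self, row: int, col: int) -> float:
        """Flow-path length of the step leaving (row, col), in metres."""
        d = self.direction[row, col]
        if d < 0:
            return 0.0
        return float(_D8_DIST[d] * self.cell_size)

    def donor_lists(self) -> list[list[int]]:
        """For each valid cell (flat index), the flat indices draining into it."""
        nr, nc = self.shape
        donors: list[list[int]] = [[] for _ in range(nr * nc)]
        rows, cols = np.nonzero(self.direction >= 0)
        for r, c in zip(rows.tolist(), cols.tolist()):
            dr, dc = D8_OFFSETS[self.direction[r, c]]
            donors[(r + dr) * nc + (c + dc)].append(r * nc + c)
        return donors

    def topological_order(self) -> np.ndarray:
        """Flat indices of valid cells, upstream before downstream.

        Raises
        ------
        ValueError
            If the pointer field contains a cycle.
        """
        nr, nc = self.shape
        indeg = np.zeros(nr * nc, dtype=np.int64)
        rows, cols = np.nonzero(self.direction >= 0)
        recv = _receiver_flat(self.direction, nc, rows, cols)
        np.add.at(indeg, recv, 1)
        valid_flat = np.nonzero(self.valid.ravel())[0]
        order = np.empty(len(valid_flat), dtype=np.int64)
        queue = deque(valid_flat[indeg[valid_flat] == 0].tolist())
        dirflat = self.direction.ravel()
        k = 0
        while queue:
            i = queue.popleft()
            order[k] = i
            k += 1
            d = dirflat[i]
            if d >= 0:
                dr, dc = D8_OFFSETS[d]
                j = i + dr * nc + dc
                indeg[j] -= 1
                if indeg[j] == 0:
                    queue.append(j)
        if k != len(valid_flat):
            raise ValueError("flow field contains a cycle")
        return order


def _receiver_flat(direction: np.ndarray, ncols: int, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    d = direction[rows, cols]
    offs = np.array(D8_OFFSETS)
    return (rows + offs[d, 0]) * ncols + (cols + offs[d, 1])


@dataclass
class AccumulationGrid:
    """Number of cells draining through each cell, including itself."""

    count: np.ndarray
    cell_size: float
    mask: np.ndarray

    @property
    def area_km2(self) -> np.ndarray:
        """Contributing area per cell in km^2."""
        return self.count * (self.cell_size / 1000.0) ** 2


def fill_depressions(dem: ElevationGrid) -> ElevationGrid:
    """Raise closed depressions so every cell drains to the grid boundary.

    Boundary-seeded priority-flood: valid cells on the grid edge or adjacent
    to nodata are seeded into a min-heap at their own elevation; interior
    cells are reached in order of increasing spill elevation and raised to
    the spill level where necessary (epsilon-free, so filled depressions
    become flats). Cells not inside a depression are returned unchanged.
    """
    values = dem.values
    mask = dem.mask
    nr, nc = values.shape
    if not mask.any():
        raise ValueError("empty terrain: all cells are nodata")

    filled = np.where(mask, values, np.nan)
    seeds = _boundary_cells(mask)
    heap: list[tuple[float, int, int, int]] = []
    closed = np.zeros((nr, nc), dtype=bool)
    counter = 0
    for r, c in seeds:
        heapq.heappush(heap, (values[r, c], counter, r, c))
        closed[r, c] = True
        counter += 1
    if not heap:
        raise ValueError("empty terrain: no valid boundary cell to drain to")

    while heap:
        z, _, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and not closed[rr, cc]:
                closed[rr, cc] = True
                zz = max(values[rr, cc], z)
                filled[rr, cc] = zz
                heapq.heappush(heap, (zz, counter, rr, cc))
                counter += 1
    return dem.like(filled)


def _boundary_cells(mask: np.ndarray) -> list[tuple[int, int]]:
    """Valid cells on the grid edge or 8-adjacent to a nodata cell."""
    nr, nc = mask.shape
    edge = np.zeros_like(mask)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    near_nodata = np.zeros_like(mask)
    inv = ~mask
    for dr, dc in D8_OFFSETS:
        shifted = np.zeros_like(mask)
        rs = slice(max(dr, 0), nr + min(dr, 0))
        rd = slice(max(-dr, 0), nr + min(-dr, 0))
        cs = slice(max(dc, 0), nc + min(dc, 0))
        cd = slice(max(-dc, 0), nc + min(-dc, 0))
        shifted[rd, cd] = inv[rs, cs]
        near_nodata |= shifted
    sel = mask & (edge | near_nodata)
    rows, cols = np.nonzero(sel)
    return list(zip(rows.tolist(), cols.tolist()))


def d8_flow_direction(filled: ElevationGrid) -> D8FlowField:
    """Steepest-descent D8 pointers on a depression-filled DEM.

    Drop is (z_cell - z_neighbour) / distance with diagonal distance
    ``cell_size * sqrt(2)``; ties take the first neighbour in the clockwise
    order starting at East. Flat cells (no positive drop) on the boundary
    drain off-grid (OUTLET); interior flat cells are resolved by BFS across
    the flat from its already-drained cells, so each flat drains toward its
    spill. An interior flat with no drained cell at its level raises
    :class:`FlatResolutionError` naming the region.
    """
    values = filled.values
    mask = filled.mask
    nr, nc = values.shape
    direction = np.full((nr, nc), NODATA_DIR, dtype=np.int8)
    z = np.where(mask, values, np.inf)

    best_drop = np.full((nr, nc), -np.inf)
    best_dir = np.full((nr, nc), -1, dtype=np.int8)
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        drop = np.full((nr, nc), -np.inf)
        rs = slice(max(dr, 0), nr + min(dr, 0))
        rd = slice(max(-dr, 0), nr + min(-dr, 0))
        cs = slice(max(dc, 0), nc + min(dc, 0))
        cd = slice(max(-dc, 0), nc + min(-dc, 0))
        drop[rd, cd] = (z[rd, cd] - z[rs, cs]) / _D8_DIST[k]
        drop[~mask] = -np.inf
        take = drop > best_drop  # strict: first neighbour in CW-from-E order wins ties
        best_drop[take] = drop[take]
        best_dir[take] = k

    downhill = mask & (best_drop > 0) & np.isfinite(best_drop)
    direction[downhill] = best_dir[downhill]

    boundary = np.zeros((nr, nc), dtype=bool)
    for r, c in _boundary_cells(mask):
        boundary[r, c] = True
    flat = mask & ~downhill
    direction[flat & boundary] = OUTLET

    unresolved = flat & ~boundary
    if unresolved.any():
        _resolve_flats(direction, z, unresolved, nr, nc)
    return D8FlowField(direction=direction, cell_size=filled.cell_size)


def _resolve_flats(direction: np.ndarray, z: np.ndarray, unresolved: np.ndarray, nr: int, nc: int) -> None:
    """Drain flat cells toward their spill by BFS from resolved cells.

    A flat cell may point to an equal-elevation neighbour that already has a
    direction; BFS from all such entry points guarantees an acyclic gradient
    across the flat (each cell points to the neighbour it was reached from).
    """
    queue: deque[tuple[int, int]] = deque()
    pending = unresolved.copy()
    rows, cols = np.nonzero(pending)
    # entry points: unresolved cells with a resolved equal-or-lower neighbour
    for r, c in zip(rows.tolist(), cols.tolist()):
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and direction[rr, cc] >= -1 and z[rr, cc] <= z[r, c]:
                direction[r, c] = k
                pending[r, c] = False
                queue.append((r, c))
                break
    while queue:
        r, c = queue.popleft()
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and pending[rr, cc] and z[rr, cc] == z[r, c]:
                # reverse direction: (rr, cc) points back to (r, c)
                direction[rr, cc] = (k + 4) % 8
                pending[rr, cc] = False
                queue.append((rr, cc))
    if pending.any():
        rows, cols = np.nonzero(pending)
        cells = list(zip(rows.tolist(), cols.tolist()))[:5]
        raise FlatResolutionError(
            f"unresolved flat region with no outlet; {int(pending.sum())} cells, e.g. {cells}"
        )


def flow_accumulation(flow: D8FlowField) -> AccumulationGrid:
    """Cells draining through each cell (including itself), one topological pass."""
    order = flow.topological_order()  # raises on cycles
    nr, nc = flow.shape
    count = np.zeros(nr * nc, dtype=np.int64)
    count[order] = 1
    dirflat = flow.direction.ravel()
    for i in order.tolist():
        d = dirflat[i]
        if d >= 0:
            dr, dc = D8_OFFSETS[d]
            count[i + dr * nc + dc] += count[i]
    return AccumulationGrid(
        count=count.reshape(nr, nc), cell_size=flow.cell_size, mask=flow.valid,
    )


def delineate_streams(acc: AccumulationGrid, threshold_km2: float) -> np.ndarray:
    """Boolean stream-cell mask: contributing area >= ``threshold_km2``.

    Accumulation is non-decreasing downstream, so the mask is automatically
    drainage-connected (a stream cell's receiver is a stream cell).
    """
    if threshold_km2 <= 0:
        raise ValueError("threshold_km2 must be positive")
    mask = acc.mask & (acc.area_km2 >= threshold_km2)
    if not mask.any():
        warnings.warn(
            f"delineation threshold {threshold_km2} km^2 exceeds the largest "
            "contributing area; stream mask is empty",
            stacklevel=2,
        )
    return mask


def catchment_mask(flow: D8FlowField, row: int, col: int) -> np.ndarray:
    """Boolean mask of all cells draining through (row, col), itself included."""
    nr, nc = flow.shape
    donors = flow.donor_lists()
    out = np.zeros(nr * nc, dtype=bool)
    start = row * nc + col
    out[start] = True
    stack = [start]
    while stack:
        i = stack.pop()
        for j in donors[i]:
            if not out[j]:
                out[j] = True
                stack.append(j)
    return out.reshape(nr, nc)


def upstream_accumulate(flow: D8FlowField, weights: np.ndarray) -> np.ndarray:
    """Sum of ``weights`` over every cell's catchment (itself included).

    One topological pass; the workhorse behind all per-reach upstream
    summaries (catchment means, upstream stream length, confluence counts).
    Cells where ``weights`` is NaN contribute 0.
    """
    nr, nc = flow.shape
    w = np.asarray(weights, dtype=float).ravel().copy()
    w[~np.isfinite(w)] = 0.0
    acc = np.zeros(nr * nc)
    order = flow.topological_order()
    acc[order] = w[order]
    dirflat = flow.direction.ravel()
    for i in order.tolist():
        d = dirflat[i]
        if d >= 0:
            dr, dc = D8_OFFSETS[d]
            acc[i + dr * nc + dc] += acc[i]
    return acc.reshape(nr, nc)
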