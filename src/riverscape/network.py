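"""Vector stream networks: tracing, reach splitting, Strahler order, GeoJSON I/O.

The raster stream mask is traced cell-center to cell-center along the D8
pointers into confluence-to-confluence segments, which are then subdivided
from their upstream end into reaches of a chosen grain length (1.0 km by
default, the modelling unit). The result is a directed acyclic network of
:class:`Reach` objects joined at :class:`Node` objects (sources, confluences,
outlets and split points), which preserves the hierarchical linear structure
of the river system and carries per-reach attributes for downstream
modelling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import ElevationGrid
from .hydro import D8FlowField

__all__ = [
    "Node",
    "Reach",
    "StreamNetwork",
    "vectorize_and_split",
    "split_segment",
    "assign_strahler",
]


@dataclass
class Node:
    id: str
    x: float
    y: float
    kind: str  # source | confluence | outlet | break


@dataclass
class Reach:
    """One stream reach: a short polyline between two network nodes."""

    id: int
    geometry: list[tuple[float, float]]  # ordered upstream -> downstream, map units
    length_km: float
    upstream_node: str
    downstream_node: str
    strahler_order: int | None = None
    outlet_cell: tuple[int, int] | None = None  # most downstream DEM cell on the reach
    attributes: dict = field(default_factory=dict)

    @property
    def midpoint(self) -> tuple[float, float]:
        """Vertex closest to half the reach length along the polyline."""
        pts = self.geometry
        cum = _cumulative_lengths(pts)
        half = cum[-1] / 2.0
        i = int(np.argmin(np.abs(np.asarray(cum) - half)))
        return pts[i]


def _cumulative_lengths(pts: list[tuple[float, float]]) -> list[float]:
    cum = [0.0]
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        cum.append(cum[-1] + math.hypot(x1 - x0, y1 - y0))
    return cum


class StreamNetwork:
    """Directed acyclic collection of reaches joined at nodes."""

    def __init__(self, reaches: list[Reach], nodes: dict[str, Node], crs_id: str = "local-projected"):
        self.reaches: dict[int, Reach] = {r.id: r for r in reaches}
        self.nodes = nodes
        self.crs_id = crs_id
        self._rebuild_topology()

    def _rebuild_topology(self) -> None:
        self._inflows: dict[str, list[int]] = {nid: [] for nid in self.nodes}
        self._outflows: dict[str, list[int]] = {nid: [] for nid in self.nodes}
        for r in self.reaches.values():
            self._inflows[r.downstream_node].append(r.id)
            self._outflows[r.upstream_node].append(r.id)

    def __len__(self) -> int:
        return len(self.reaches)

    @property
    def total_length_km(self) -> float:
        return float(sum(r.length_km for r in self.reaches.values()))

    def inflow_reaches(self, reach_id: int) -> list[int]:
        return self._inflows[self.reaches[reach_id].upstream_node]

    def downstream_reach(self, reach_id: int) -> int | None:
        out = self._outflows[self.reaches[reach_id].downstream_node]
        if not out:
            return None
        if len(out) > 1:
            raise ValueError(f"node {self.reaches[reach_id].downstream_node} has multiple outflows")
        return out[0]

    def confluence_nodes(self) -> list[Node]:
        return [n for nid, n in self.nodes.items() if len(self._inflows[nid]) >= 2]

    def source_reaches(self) -> list[int]:
        return [rid for rid, r in self.reaches.items() if not self._inflows[r.upstream_node]]

    def topological_reach_order(self) -> list[int]:
        """Reach ids, upstream before downstream. Raises on cycles."""
        indeg = {rid: len(self.inflow_reaches(rid)) for rid in self.reaches}
        queue = [rid for rid, d in indeg.items() if d == 0]
        order: list[int] = []
        while queue:
            rid = queue.pop()
            order.append(rid)
            nxt = self.downstream_reach(rid)
            if nxt is not None:
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    queue.append(nxt)
        if len(order) != len(self.reaches):
            raise ValueError("stream network contains a cycle")
        return order

    def attribute_table(self):
        """Per-reach attributes as a DataFrame indexed by reach id."""
        import pandas as pd

        rows = {rid: dict(r.attributes) for rid, r in self.reaches.items()}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "reach_id"
        return df

    # ------------------------------------------------------------------ I/O

    def to_geojson(self, path: str | Path | None = None) -> dict:
        features = []
        for r in self.reaches.values():
            props = {
                "id": r.id,
                "order": r.strahler_order,
                "length_km": r.length_km,
                "upstream_node": r.upstream_node,
                "downstream_node": r.downstream_node,
                "outlet_cell": list(r.outlet_cell) if r.outlet_cell else None,
            }
            props.update(r.attributes)
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(p) for p in r.geometry]},
                "properties": props,
            })
        fc = {
            "type": "FeatureCollection",
            "features": features,
            "riverscape": {
                "crs_id": self.crs_id,
                "nodes": {nid: [n.x, n.y, n.kind] for nid, n in self.nodes.items()},
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(fc))
        return fc

    @classmethod
    def from_geojson(cls, source: str | Path | dict) -> "StreamNetwork":
        fc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        meta = fc.get("riverscape", {})
        nodes = {
            nid: Node(nid, x, y, kind)
            for nid, (x, y, kind) in meta.get("nodes", {}).items()
        }
        reaches = []
        for feat in fc["features"]:
            p = dict(feat["properties"])
            oc = p.pop("outlet_cell", None)
            r = Reach(
                id=int(p.pop("id")),
                geometry=[tuple(c) for c in feat["geometry"]["coordinates"]],
                length_km=float(p.pop("length_km")),
                upstream_node=p.pop("upstream_node"),
                downstream_node=p.pop("downstream_node"),
                strahler_order=p.pop("order", None),
                outlet_cell=tuple(oc) if oc else None,
                attributes=p,
            )
            reaches.append(r)
        return cls(reaches, nodes, crs_id=meta.get("crs_id", "local-projected"))


# ------------------------------------------------------------- vectorization


def vectorize_and_split(
    mask: np.ndarray,
    flow: D8FlowField,
    dem: ElevationGrid,
    grain_km: float = 1.0,
) -> StreamNetwork:
    """Trace the stream mask into polylines and split them into reaches.

    Segments run from sources/confluences to the next confluence or outlet
    along the flow pointers, with vertices at cell centers. Each segment is
    then cut from its upstream end into pieces of ``grain_km``; a terminal
    remainder of at least 1% of the grain becomes its own reach, a smaller
    one is merged into the preceding reach.
    """
    if grain_km <= 0:
        raise ValueError("grain_km must be positive")
    if not np.asarray(mask, dtype=bool).any():
        raise ValueError("empty stream mask: nothing to vectorize")
    mask = np.asarray(mask, dtype=bool)
    nr, nc = mask.shape

    # stream-donor counts per stream cell
    n_stream_donors = np.zeros((nr, nc), dtype=np.int32)
    rows, cols = np.nonzero(mask)
    stream_cells = list(zip(rows.tolist(), cols.tolist()))
    for r, c in stream_cells:
        rec = flow.receiver(r, c)
        if rec is not None and mask[rec]:
            n_stream_donors[rec] += 1

    is_junction = mask & (n_stream_donors >= 2)
    is_head = mask & (n_stream_donors == 0)

    nodes: dict[str, Node] = {}
    cell_node: dict[tuple[int, int], str] = {}

    def node_at_cell(cell: tuple[int, int], kind: str) -> str:
        if cell in cell_node:
            return cell_node[cell]
        nid = f"n{len(nodes)}"
        x, y = dem.cell_center(*cell)
        nodes[nid] = Node(nid, x, y, kind)
        cell_node[cell] = nid
        return nid

    starts = sorted(
        [(r, c) for r, c in stream_cells if is_head[r, c] or is_junction[r, c]]
    )
    reaches: list[Reach] = []
    next_id = 0
    for start in starts:
        kind = "confluence" if is_junction[start] else "source"
        path = [start]
        cur = start
        while True:
            rec = flow.receiver(*cur)
            if rec is None or not mask[rec]:
                end_kind = "outlet"
                end_cell = cur
                break
            path.append(rec)
            if is_junction[rec]:
                end_kind = "confluence"
                end_cell = rec
                break
            cur = rec
        if len(path) < 2:
            continue  # degenerate: junction cell is itself the outlet
        up_node = node_at_cell(start, kind)
        down_node = node_at_cell(end_cell, end_kind)
        verts = [dem.cell_center(r, c) for r, c in path]
        pieces = split_segment(verts, grain_km, cells=path)
        prev_node = up_node
        for j, (pverts, plen_km, pcells) in enumerate(pieces):
            last = j == len(pieces) - 1
            if last:
                nxt_node = down_node
            else:
                nid = f"n{len(nodes)}"
                nodes[nid] = Node(nid, pverts[-1][0], pverts[-1][1], "break")
                nxt_node = nid
            outlet_cell = pcells[-1] if pcells else dem.index_of(*pverts[-1])
            reaches.append(
                Reach(
                    id=next_id,
                    geometry=pverts,
                    length_km=plen_km,
                    upstream_node=prev_node,
                    downstream_node=nxt_node,
                    outlet_cell=outlet_cell,
                )
            )
            next_id += 1
            prev_node = nxt_node

    net = StreamNetwork(reaches, nodes, crs_id=dem.crs_id)
    return assign_strahler(net)


def split_segment(
    vertices: list[tuple[float, float]],
    grain_km: float,
    cells: list[tuple[int, int]] | None = None,
    min_remainder_frac: float = 0.01,
) -> list[tuple[list[tuple[float, float]], float, list[tuple[int, int]]]]:
    """Cut a polyline into grain-length pieces from its upstream end.

    Returns a list of (vertices, length_km, cells) per piece, where ``cells``
    are the DEM cells of the original vertices falling in the piece (cut
    points are interpolated and carry no cell). The terminal remainder is its
    own piece when it is at least ``min_remainder_frac`` of the grain, and is
    merged into the previous piece otherwise.
    """
    grain_m = grain_km * 1000.0
    cum = _cumulative_lengths(vertices)
    total = cum[-1]
    if total <= 0:
        raise ValueError("segment has zero length")
    if cells is None:
        cells = [None] * len(vertices)  # type: ignore[list-item]

    n_full = int(math.floor(total / grain_m + 1e-12))
    remainder = total - n_full * grain_m
    cuts = [i * grain_m for i in range(1, n_full + 1)]
    if cuts and cuts[-1] >= total - 1e-9:
        cuts = cuts[:-1]  # total is an exact multiple of the grain
        remainder = grain_m
    if cuts and remainder < min_remainder_frac * grain_m:
        cuts = cuts[:-1]  # merge sliver into the previous piece

    pieces: list[tuple[list[tuple[float, float]], float, list[tuple[int, int]]]] = []
    cur_verts: list[tuple[float, float]] = [vertices[0]]
    cur_cells: list[tuple[int, int]] = [cells[0]] if cells[0] is not None else []
    cut_iter = iter(cuts + [float("inf")])
    next_cut = next(cut_iter)
    piece_start = 0.0
    for i in range(1, len(vertices)):
        seg_start, seg_end = cum[i - 1], cum[i]
        while next_cut < seg_end - 1e-9:
            t = (next_cut - seg_start) / (seg_end - seg_start)
            px = vertices[i - 1][0] + t * (vertices[i][0] - vertices[i - 1][0])
            py = vertices[i - 1][1] + t * (vertices[i][1] - vertices[i - 1][1])
            cur_verts.append((px, py))
            pieces.append((cur_verts, (next_cut - piece_start) / 1000.0, cur_cells))
            cur_verts = [(px, py)]
            cur_cells = []
            piece_start = next_cut
            next_cut = next(cut_iter)
        if abs(next_cut - seg_end) <= 1e-9:
            cur_verts.append(vertices[i])
            if cells[i] is not None:
                cur_cells.append(cells[i])
            pieces.append((cur_verts, (next_cut - piece_start) / 1000.0, cur_cells))
            cur_verts = [vertices[i]]
            cur_cells = [cells[i]] if cells[i] is not None else []
            piece_start = next_cut
            next_cut = next(cut_iter)
        else:
            cur_verts.append(vertices[i])
            if cells[i] is not None:
                cur_cells.append(cells[i])
    if len(cur_verts) >= 2:
        pieces.append((cur_verts, (total - piece_start) / 1000.0, cur_cells))
    # inherit upstream cells for pieces that contain no original vertex
    for k in range(len(pieces)):
        if not pieces[k][2]:
            donor = pieces[k - 1][2] if k > 0 else []
            if donor:
                pieces[k] = (pieces[k][0], pieces[k][1], [donor[-1]])
    return pieces


def assign_strahler(network: StreamNetwork) -> StreamNetwork:
    """Strahler order per reach, propagated down the reach DAG.

    Source reaches get order 1; at a confluence the outflow takes the maximum
    inflow order, incremented when two or more inflows share that maximum;
    chain reaches between confluences inherit their single inflow's order.
    """
    for rid in network.topological_reach_order():
        inflows = network.inflow_reaches(rid)
        if not inflows:
            network.reaches[rid].strahler_order = 1
        else:
            orders = [network.reaches[i].strahler_order for i in inflows]
            top = max(orders)
            network.reaches[rid].strahler_order = top + 1 if orders.count(top) >= 2 else top
    return network
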