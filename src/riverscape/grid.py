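"""Raster elevation grids and plain-text raster I/O.

The grid container used throughout the hydrology stack. Rasters are read and
written as ESRI ASCII grids (``.asc``), a single-band plain-text format that
carries cell size, origin and nodata; all coordinates are assumed to be in a
projected CRS with square cells (geographic/degree grids are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationGrid", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclass
class ElevationGrid:
    """A single-band raster in a projected coordinate system.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values in map units (metres for elevation). Cells flagged
        invalid by ``mask`` may hold any value.
    cell_size : float
        Square cell edge length in metres (> 0).
    origin : (float, float)
        Map coordinates (x, y) of the grid's upper-left *corner*.
    mask : ndarray of bool
        True where the cell is valid; False marks nodata.
    crs_id : str
        Opaque identifier of the projected CRS (e.g. an EPSG code string).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    crs_id: str = "local-projected"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.mask = self.mask & np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell (row, col)."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        return (
            x0 + (np.asarray(cols) + 0.5) * self.cell_size,
            y0 - (np.asarray(rows) + 0.5) * self.cell_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing map point (x, y); may be off-grid."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.index_of(x, y)
        nr, nc = self.shape
        return 0 <= row < nr and 0 <= col < nc and bool(self.mask[row, col])

    def value_at(self, x: float, y: float) -> float:
        row, col = self.index_of(x, y)
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise IndexError(f"point ({x}, {y}) is outside the grid")
        return float(self.values[row, col])

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "ElevationGrid":
        """A new grid co-registered with this one."""
        return ElevationGrid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            mask=self.mask.copy() if mask is None else mask,
            crs_id=self.crs_id,
        )

    def aligned_with(self, other: "ElevationGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


def read_ascii_grid(path: str | Path, crs_id: str = "local-projected") -> ElevationGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key!r}")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"ASCII grid {path}: data shape {values.shape} != header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    mask = ~np.isclose(values, nodata) & np.isfinite(values)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return ElevationGrid(values=values, cell_size=cell, origin=origin, mask=mask, crs_id=crs_id)


def write_ascii_grid(grid: ElevationGrid, path: str | Path, nodata: float = _DEFAULT_NODATA) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    path = Path(path)
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    out = np.where(grid.mask, grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {y0 - nrows * grid.cell_size:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, out, fmt="%.6f")
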