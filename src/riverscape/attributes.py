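"""Per-reach topographic and environmental predictors.

Every reach receives the habitat covariates used by the niche models: local
channel descriptors (gradient, sinuosity) read off the reach polyline, and
catchment-supported summaries (contributing area, confluence density, stream
density, mean upstream slope, upstream means of environmental rasters)
computed over the set of cells draining through the reach. Catchment
summaries are computed for all reaches at once with a single topological
accumulation pass per quantity, so attribution stays linear in grid size.

A greedy Pearson-correlation filter (|r| < 0.7 retained) reduces the
candidate predictor set before model fitting, preferring variables earlier
in a caller-supplied priority order.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .grid import ElevationGrid
from .hydro import D8FlowField, catchment_mask, flow_accumulation, upstream_accumulate
from .network import Reach, StreamNetwork

__all__ = [
    "reach_gradient",
    "sinuosity",
    "confluence_density",
    "stream_density",
    "upstream_summary",
    "slope_grid",
    "correlation_filter",
    "build_predictor_table",
    "attach_attributes",
]


def reach_gradient(reach: Reach, dem: ElevationGrid) -> float:
    """Channel gradient in % slope: 100 x (drop between endpoints) / path length.

    Apparent uphill flow (DEM noise) is clamped to 0 with a warning.
    """
    (x0, y0), (x1, y1) = reach.geometry[0], reach.geometry[-1]
    for x, y in ((x0, y0), (x1, y1)):
        if not dem.contains(x, y):
            raise ValueError(f"reach {reach.id} endpoint ({x}, {y}) is off-grid or nodata")
    z_up = dem.value_at(x0, y0)
    z_down = dem.value_at(x1, y1)
    grad = 100.0 * (z_up - z_down) / (reach.length_km * 1000.0)
    if grad < 0:
        warnings.warn(
            f"reach {reach.id}: negative gradient {grad:.3f}% clamped to 0", stacklevel=2
        )
        return 0.0
    return grad


def sinuosity(reach: Reach) -> float:
    """Path length divided by straight-line distance between endpoints (>= 1)."""
    if len(reach.geometry) < 2:
        raise ValueError("sinuosity requires at least 2 vertices")
    (x0, y0), (x1, y1) = reach.geometry[0], reach.geometry[-1]
    chord = math.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        raise ValueError(f"closed reach {reach.id}: coincident endpoints")
    return reach.length_km * 1000.0 / chord


def _reach_catchment(reach: Reach, flow: D8FlowField) -> np.ndarray:
    if reach.outlet_cell is None:
        raise ValueError(f"reach {reach.id} has no outlet cell; was it traced from a grid?")
    return catchment_mask(flow, *reach.outlet_cell)


def confluence_density(network: StreamNetwork, reach: Reach, flow: D8FlowField,
                       dem: ElevationGrid) -> float:
    """Confluence nodes in the reach's upstream catchment per km^2."""
    cm = _reach_catchment(reach, flow)
    area = cm.sum() * dem.cell_area_km2
    if area <= 0:
        raise ValueError(f"reach {reach.id}: zero catchment area")
    n = 0
    for node in network.confluence_nodes():
        r, c = dem.index_of(node.x, node.y)
        if 0 <= r < cm.shape[0] and 0 <= c < cm.shape[1] and cm[r, c]:
            n += 1
    return n / area


def stream_density(network: StreamNetwork, reach: Reach, flow: D8FlowField,
                   dem: ElevationGrid, stream_mask: np.ndarray) -> float:
    """Stream length (km) in the reach's upstream catchment per km^2."""
    cm = _reach_catchment(reach, flow)
    area = cm.sum() * dem.cell_area_km2
    if area <= 0:
        raise ValueError(f"reach {reach.id}: zero catchment area")
    length_m = _stream_length_in(cm, flow, stream_mask)
    return (length_m / 1000.0) / area


def _stream_length_in(cm: np.ndarray, flow: D8FlowField, stream_mask: np.ndarray) -> float:
    """Total cell-to-cell stream length (m) for steps fully inside mask ``cm``."""
    total = 0.0
    rows, cols = np.nonzero(stream_mask & cm)
    for r, c in zip(rows.tolist(), cols.tolist()):
        rec = flow.receiver(r, c)
        if rec is not None and stream_mask[rec] and cm[rec]:
            total += flow.step_length_m(r, c)
    return total


def upstream_summary(raster: np.ndarray | ElevationGrid, flow: D8FlowField,
                     reach: Reach, statistic: str = "mean") -> float:
    """Summary of a co-registered raster over the reach's upstream catchment.

    Raster nodata (NaN) cells are ignored; a catchment that is entirely
    nodata yields NaN with a warning.
    """
    if statistic != "mean":
        raise ValueError("only the 'mean' statistic is supported")
    values = raster.values if isinstance(raster, ElevationGrid) else np.asarray(raster, float)
    if isinstance(raster, ElevationGrid):
        values = np.where(raster.mask, values, np.nan)
    if values.shape != flow.shape:
        raise ValueError("raster is not co-registered with the flow grid")
    cm = _reach_catchment(reach, flow)
    vals = values[cm]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"reach {reach.id}: catchment entirely nodata in raster", stacklevel=2)
        return float("nan")
    return float(vals.mean())


def slope_grid(dem: ElevationGrid) -> np.ndarray:
    """Terrain slope by Horn's 3x3 central difference, in degrees x 100."""
    z = np.where(dem.mask, dem.values, np.nan)
    zp = np.pad(z, 1, mode="edge")
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * dem.cell_size)
    dzdy = ((sw + 2 * s_ + se) - (nw + 2 * n_ + ne)) / (8 * dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy))) * 100.0
    return np.where(dem.mask, slope, np.nan)


def correlation_filter(
    table: pd.DataFrame,
    r_max: float = 0.7,
    priority: list[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Greedy collinearity filter: keep a variable iff |Pearson r| with every
    already-kept variable is below ``r_max``, scanning in priority order.

    Constant columns are dropped (with a warning) before correlation.
    Returns the filtered table and a report listing each dropped variable,
    the kept variable that triggered the drop, and the offending r.
    """
    if len(table) < 2:
        raise ValueError("correlation filter needs at least 2 rows")
    if not 0 < r_max < 1:
        raise ValueError("r_max must be in (0, 1)")
    order = list(priority) if priority is not None else list(table.columns)
    unknown = set(order) - set(table.columns)
    if unknown:
        raise KeyError(f"priority names not in table: {sorted(unknown)}")
    order += [c for c in table.columns if c not in order]

    report: list[dict] = []
    kept: list[str] = []
    for col in order:
        x = table[col].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"predictor {col!r} is constant; dropped before correlation",
                          stacklevel=2)
            report.append({"dropped": col, "kept": None, "r": float("nan"),
                           "reason": "constant"})
            continue
        clash = None
        for kcol in kept:
            r = table[col].corr(table[kcol])
            if abs(r) >= r_max:
                clash = (kcol, float(r))
                break
        if clash is None:
            kept.append(col)
        else:
            report.append({"dropped": col, "kept": clash[0], "r": clash[1],
                           "reason": "correlated"})
    return table[kept], report


def build_predictor_table(
    network: StreamNetwork,
    dem: ElevationGrid,
    flow: D8FlowField,
    stream_mask: np.ndarray,
    env_rasters: dict[str, np.ndarray | ElevationGrid] | None = None,
    filled: ElevationGrid | None = None,
) -> pd.DataFrame:
    """All per-reach predictors, one row per reach (index = reach id).

    Catchment-supported quantities use one upstream-accumulation pass per
    quantity rather than a per-reach flood fill, so the cost is
    O(grid + reaches) regardless of network size. ``filled`` (the
    depression-filled DEM) is used for the slope grid when given; otherwise
    the raw DEM is used.
    """
    nr, nc = flow.shape
    acc = flow_accumulation(flow)
    count_flat = acc.count

    # confluence indicator per cell
    conf = np.zeros((nr, nc))
    for node in network.confluence_nodes():
        r, c = dem.index_of(node.x, node.y)
        if 0 <= r < nr and 0 <= c < nc:
            conf[r, c] = 1.0
    conf_up = upstream_accumulate(flow, conf)

    # incoming stream-step length per cell
    step_w = np.zeros((nr, nc))
    rows, cols = np.nonzero(stream_mask)
    for r, c in zip(rows.tolist(), cols.tolist()):
        rec = flow.receiver(r, c)
        if rec is not None and stream_mask[rec]:
            step_w[rec] += flow.step_length_m(r, c)
    len_up = upstream_accumulate(flow, step_w)

    slope = slope_grid(filled if filled is not None else dem)
    summaries = {"mean_upstream_slope": slope}
    if env_rasters:
        for name, rast in env_rasters.items():
            v = rast.values if isinstance(rast, ElevationGrid) else np.asarray(rast, float)
            if isinstance(rast, ElevationGrid):
                if not rast.aligned_with(dem):
                    raise ValueError(f"environmental raster {name!r} is not co-registered "
                                     "with the DEM (resampling is out of scope)")
                v = np.where(rast.mask, v, np.nan)
            summaries[f"upstr_{name}"] = v
    sums, ns = {}, {}
    for name, v in summaries.items():
        finite = np.isfinite(v)
        sums[name] = upstream_accumulate(flow, np.where(finite, v, 0.0))
        ns[name] = upstream_accumulate(flow, finite.astype(float))

    records = []
    for rid, reach in network.reaches.items():
        oc = reach.outlet_cell
        if oc is None:
            raise ValueError(f"reach {rid} has no outlet cell")
        r, c = oc
        area = count_flat[r, c] * dem.cell_area_km2
        with warnings.catch_warnings():  # uphill-noise clamps are routine here
            warnings.simplefilter("ignore")
            grad = reach_gradient(reach, dem)
        rec = {
            "reach_id": rid,
            "gradient_pct": grad,
            "sinuosity": sinuosity(reach),
            "catchment_area_km2": area,
            "confluence_density": conf_up[r, c] / area,
            "stream_density": (len_up[r, c] / 1000.0) / area,
            "strahler_order": reach.strahler_order,
        }
        for name in summaries:
            n = ns[name][r, c]
            rec[name] = sums[name][r, c] / n if n > 0 else float("nan")
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("reach_id")


def attach_attributes(network: StreamNetwork, table: pd.DataFrame) -> StreamNetwork:
    """Mirror a predictor table into each reach's ``attributes`` dict."""
    for rid, row in table.iterrows():
        network.reaches[int(rid)].attributes.update(row.to_dict())
    return network
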