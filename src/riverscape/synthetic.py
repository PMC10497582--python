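"""Seeded synthetic landscapes, environmental rasters and virtual species.

Everything the pipeline consumes can be generated deterministically from a
seed: hydrologically drainable terrains (a tilted plane, a V-shaped valley
with a single main stem, or a dendritic fractal surface built from
multi-scale smoothed noise on a regional tilt), smooth environmental fields
(with an optional elevation-lapse temperature), and virtual species whose
true suitability over the reach network is a known logistic response —
the ground truth for model-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import ElevationGrid
from .maxent import OccurrenceSet
from .network import StreamNetwork

__all__ = [
    "SyntheticLandscapeSpec",
    "VirtualSpeciesSpec",
    "generate_dem",
    "generate_env_rasters",
    "simulate_virtual_species",
]


@dataclass
class SyntheticLandscapeSpec:
    rows: int = 256
    cols: int = 256
    cell_size: float = 50.0  # m
    kind: str = "dendritic_fractal"  # tilted_plane | valley_v | dendritic_fractal
    noise_amplitude: float = 30.0  # m
    relief: float = 500.0  # m of regional elevation range
    base_elevation: float = 1000.0  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.kind not in {"tilted_plane", "valley_v", "dendritic_fractal"}:
            raise ValueError(f"unknown terrain kind {self.kind!r}")


def generate_dem(spec: SyntheticLandscapeSpec) -> ElevationGrid:
    """Deterministic synthetic DEM of the requested terrain kind.

    ``tilted_plane`` is noise-free (and therefore depression-free: filling
    is an identity on it); ``valley_v`` drains a single main stem east along
    the valley axis; ``dendritic_fractal`` is multi-scale smoothed noise over
    an eastward regional tilt, yielding a branching drainage pattern.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols
    r = np.arange(rows)[:, None].astype(float)
    c = np.arange(cols)[None, :].astype(float)

    if spec.kind == "tilted_plane":
        z = spec.base_elevation + spec.relief * (cols - 1 - c) / max(cols - 1, 1)
        z = np.broadcast_to(z, (rows, cols)).copy()
    elif spec.kind == "valley_v":
        mid = (rows - 1) / 2.0
        cross = spec.relief * np.abs(r - mid) / max(mid, 1.0)
        along = 0.4 * spec.relief * (cols - 1 - c) / max(cols - 1, 1)
        noise = gaussian_filter(rng.normal(size=(rows, cols)), sigma=3)
        noise *= 0.0 if spec.noise_amplitude == 0 else spec.noise_amplitude / max(np.abs(noise).max(), 1e-12)
        # keep the noise well below the cross-valley gradient per cell
        z = spec.base_elevation + cross + along + 0.1 * noise
    else:  # dendritic_fractal
        z = np.zeros((rows, cols))
        for sigma, weight in ((2, 0.15), (8, 0.35), (32, 0.5)):
            f = gaussian_filter(rng.normal(size=(rows, cols)), sigma=sigma)
            f /= max(np.abs(f).max(), 1e-12)
            z += weight * f
        z *= spec.noise_amplitude / 0.5 * 4.0  # multi-scale relief
        z += spec.base_elevation + spec.relief * (cols - 1 - c) / max(cols - 1, 1)
    return ElevationGrid(values=z, cell_size=spec.cell_size,
                         origin=(0.0, rows * spec.cell_size),
                         crs_id="synthetic-projected")


def generate_env_rasters(
    grid: ElevationGrid,
    names: list[str],
    seed: int = 0,
    kinds: dict[str, str] | None = None,
) -> dict[str, ElevationGrid]:
    """Smooth co-registered environmental rasters, one per requested name.

    ``kinds`` maps a name to 'smooth' (Gaussian-filtered noise, the default),
    'lapse' (elevation-correlated, lapse-like cooling with height; the
    default for names containing 'temp'), or 'constant'. Value ranges are
    name-aware: temperatures in deg C, precipitation in mm, landcover in %,
    soil carbon in %.
    """
    rng = np.random.default_rng(seed)
    rows, cols = grid.shape
    out: dict[str, ElevationGrid] = {}
    for name in names:
        kind = (kinds or {}).get(name) or ("lapse" if "temp" in name.lower() else "smooth")
        smooth = gaussian_filter(rng.normal(size=(rows, cols)), sigma=max(rows, cols) / 10)
        rngspan = max(np.ptp(smooth), 1e-12)
        unit = (smooth - smooth.min()) / rngspan  # in [0, 1]
        if kind == "constant":
            vals = np.full((rows, cols), 1.0)
        elif kind == "lapse":
            # 6.5 deg C / km lapse on elevation plus weak local variation
            vals = 30.0 - 6.5 * grid.values / 1000.0 + 1.0 * (unit - 0.5)
        elif "precip" in name.lower():
            vals = 300.0 + 1500.0 * unit
        elif "soil" in name.lower():
            vals = 10.0 * unit
        elif any(tag in name.lower() for tag in ("tree", "shrub", "herb", "cover")):
            vals = 100.0 * unit
        else:
            vals = unit
        out[name] = grid.like(vals)
    return out


@dataclass
class VirtualSpeciesSpec:
    """Known truth for a simulated species over reach predictors.

    The true suitability is logistic(intercept + sum linear + sum quadratic)
    on standardized predictors; the intercept is solved so mean suitability
    equals ``prevalence``. Presences are drawn without replacement with
    probability proportional to suitability, and positional uncertainties
    are kept at or below 100 m so occurrence cleaning retains them.
    """

    species: str = "virtual"
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    prevalence: float = 0.3
    n_presence: int = 100
    seed: int = 0


def simulate_virtual_species(
    network: StreamNetwork,
    table: pd.DataFrame,
    spec: VirtualSpeciesSpec,
) -> tuple[OccurrenceSet, pd.Series]:
    """Sample occurrences from a known suitability surface on the network.

    Returns the occurrence set (coordinates at reach midpoints with small
    jitter) and the true per-reach suitability.
    """
    if spec.n_presence > len(table):
        raise ValueError(
            f"n_presence={spec.n_presence} exceeds reach count {len(table)}"
        )
    rng = np.random.default_rng(spec.seed)
    lp = np.zeros(len(table))
    for v, coef in spec.linear.items():
        z = _standardize(table[v])
        lp += coef * z
    for v, coef in spec.quadratic.items():
        z = _standardize(table[v])
        lp += coef * z ** 2

    if np.ptp(lp) == 0:
        intercept = float(np.log(spec.prevalence / (1 - spec.prevalence)))
    else:
        intercept = optimize.brentq(
            lambda a: expit(lp + a).mean() - spec.prevalence, -60.0, 60.0
        )
    suit = pd.Series(expit(lp + intercept), index=table.index, name="true_suitability")

    p = suit.to_numpy() / suit.sum()
    ids = table.index.to_numpy()
    chosen = rng.choice(len(ids), size=spec.n_presence, replace=False, p=p)
    records = []
    for i in chosen.tolist():
        rid = int(ids[i])
        x, y = network.reaches[rid].midpoint
        jitter = rng.uniform(-5.0, 5.0, size=2)  # small: stays within the cell
        records.append({
            "x": x + jitter[0],
            "y": y + jitter[1],
            "uncertainty_m": float(rng.uniform(5.0, 95.0)),
            "source": "virtual",
            "reach_id": rid,
        })
    occ = OccurrenceSet(species=spec.species, records=pd.DataFrame.from_records(records))
    return occ, suit


def _standardize(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
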