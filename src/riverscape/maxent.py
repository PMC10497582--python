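"""Presence-background maximum-entropy habitat modelling.

Implements the full presence-background MaxEnt pipeline on stream reaches:
occurrence cleaning, buffered background sampling, feature expansion
(linear, quadratic, product, hinge, threshold with background-fitted min-max
normalizers), L1-penalized Gibbs-likelihood fitting, and continuous
suitability prediction on the cloglog scale.

Model and penalty
-----------------
With features f(x) in [0, 1]^J and background reaches B, the model is the
Gibbs distribution q(x) = exp(beta' f(x)) / Z over B. Fitting maximizes the
penalized presence log-likelihood

    (1/n) sum_i beta' f(x_i)  -  log Z  -  sum_j m * lambda_j * |beta_j|,

where the per-feature weights lambda_j follow the published MaxEnt defaults
(class- and sample-size-dependent base beta, scaled by the feature's presence
standard deviation over sqrt(n)) and m is the user-facing regularization
multiplier. The optimizer is cyclic coordinate descent with proximal Newton
updates (soft-thresholding), which converges to the unique optimum of this
convex objective.

Raw output exp(beta'f - log Z) sums to 1 over the background; the cloglog
suitability 1 - exp(-exp(H) * raw), with H the entropy of the fitted
background distribution, is the default display scale and is strictly
increasing in raw.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from shapely.geometry import LineString, Point
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import ElevationGrid
from .network import StreamNetwork

__all__ = [
    "OccurrenceSet",
    "FeatureExpansion",
    "MaxEntModel",
    "ConvergenceError",
    "clean_occurrences",
    "assign_to_reaches",
    "sample_background",
    "expand_features",
    "fit_maxent",
    "predict_suitability",
    "default_feature_classes",
    "response_curve",
]


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, gradient_norm: float):
        super().__init__(msg)
        self.gradient_norm = gradient_norm


@dataclass
class OccurrenceSet:
    """Species occurrence records: coordinates plus positional uncertainty (m)."""

    species: str
    records: pd.DataFrame  # columns: x, y, uncertainty_m, source

    def __post_init__(self) -> None:
        for col in ("x", "y", "uncertainty_m"):
            if col not in self.records.columns:
                raise ValueError(f"occurrence table missing column {col!r}")
        if "source" not in self.records.columns:
            self.records = self.records.assign(source="unknown")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path: str | Path, species: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if species is None:
            species = str(df["species"].iloc[0]) if "species" in df.columns else Path(path).stem
        if "species" in df.columns:
            df = df[df["species"] == species].drop(columns="species")
        return cls(species=species, records=df.reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.records.assign(species=self.species).to_csv(path, index=False)


def clean_occurrences(
    raw: OccurrenceSet,
    grid: ElevationGrid,
    max_uncertainty_m: float = 100.0,
) -> tuple[OccurrenceSet, dict[str, int]]:
    """Drop imprecise, off-grid and per-cell duplicate records.

    Records with positional uncertainty above ``max_uncertainty_m`` (100 m by
    default) are discarded, then records falling outside the grid or on
    nodata, then all but the first record per grid cell. Returns the cleaned
    set and a report of counts per drop reason.
    """
    df = raw.records.reset_index(drop=True)
    report = {"uncertain": 0, "off_grid": 0, "duplicate": 0, "kept": 0}

    ok_unc = df["uncertainty_m"] <= max_uncertainty_m
    report["uncertain"] = int((~ok_unc).sum())
    df = df[ok_unc]

    on_grid = df.apply(lambda row: grid.contains(row["x"], row["y"]), axis=1) if len(df) else pd.Series(dtype=bool)
    report["off_grid"] = int((~on_grid).sum()) if len(df) else 0
    df = df[on_grid] if len(df) else df

    if len(df):
        cells = df.apply(lambda row: grid.index_of(row["x"], row["y"]), axis=1)
        dup = cells.duplicated()
        report["duplicate"] = int(dup.sum())
        df = df[~dup]
    report["kept"] = len(df)
    if report["kept"] == 0:
        raise ValueError(f"no usable occurrences for {raw.species!r} after cleaning: {report}")
    return OccurrenceSet(species=raw.species, records=df.reset_index(drop=True)), report


def _reach_geoms(network: StreamNetwork) -> tuple[list[LineString], list[int]]:
    ids = list(network.reaches)
    return [LineString(network.reaches[rid].geometry) for rid in ids], ids


def assign_to_reaches(occ: OccurrenceSet, network: StreamNetwork,
                      max_snap_km: float = 1.0) -> pd.Series:
    """Reach id nearest to each occurrence (NaN beyond ``max_snap_km``)."""
    geoms, ids = _reach_geoms(network)
    tree = STRtree(geoms)
    out = []
    for _, row in occ.records.iterrows():
        p = Point(row["x"], row["y"])
        idx = tree.nearest(p)
        if geoms[idx].distance(p) <= max_snap_km * 1000.0:
            out.append(ids[idx])
        else:
            out.append(np.nan)
    return pd.Series(out, index=occ.records.index, name="reach_id")


def sample_background(
    occ: OccurrenceSet,
    network: StreamNetwork,
    buffer_km: float,
    n_background: int = 10_000,
    seed: int = 0,
) -> list[int]:
    """Seeded uniform sample of reaches intersecting the occurrence buffers.

    Background reaches are drawn without replacement from all reaches whose
    geometry intersects the union of ``buffer_km`` disks around the
    occurrences; when fewer candidates than ``n_background`` exist, all are
    returned.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    pts = [Point(x, y) for x, y in zip(occ.records["x"], occ.records["y"])]
    region = unary_union([p.buffer(buffer_km * 1000.0) for p in pts])
    geoms, ids = _reach_geoms(network)
    candidates = [rid for g, rid in zip(geoms, ids) if g.intersects(region)]
    if not candidates:
        raise ValueError(f"no reach within {buffer_km} km of any occurrence")
    if n_background >= len(candidates):
        return candidates
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates), size=n_background, replace=False)
    return [candidates[i] for i in sorted(pick.tolist())]


# ------------------------------------------------------------------ features


@dataclass
class FeatureExpansion:
    """Feature-class specification plus background-fitted normalizers.

    ``classes`` is a subset of 'lqpht' (linear, quadratic, product, hinge,
    threshold). Normalizers are per-variable background min/max; every
    feature maps background values into [0, 1].
    """

    classes: str = "lq"
    n_hinge_knots: int = 50
    n_threshold_knots: int = 50
    clamp: bool = True  # clamp transfer values to the training (background) range
    minima: dict[str, float] = field(default_factory=dict)
    maxima: dict[str, float] = field(default_factory=dict)
    variables: list[str] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.classes) - set("lqpht")
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")

    def fit(self, background: pd.DataFrame) -> "FeatureExpansion":
        """Learn min-max normalizers from the background table."""
        self.variables = list(background.columns)
        self.degenerate = []
        for v in self.variables:
            lo, hi = float(background[v].min()), float(background[v].max())
            if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
                warnings.warn(f"predictor {v!r} is degenerate (max == min); "
                              "its features are omitted", stacklevel=2)
                self.degenerate.append(v)
                continue
            self.minima[v], self.maxima[v] = lo, hi
        return self

    @property
    def active_variables(self) -> list[str]:
        return [v for v in self.variables if v not in self.degenerate]

    def _scaled(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for v in self.active_variables:
            if v not in rows.columns:
                raise KeyError(f"missing predictor {v!r} in input rows")
            lo, hi = self.minima[v], self.maxima[v]
            s = (rows[v].to_numpy(dtype=float) - lo) / (hi - lo)
            out[v] = np.clip(s, 0.0, 1.0) if self.clamp else s
        return pd.DataFrame(out, index=rows.index)

    def knots(self, n: int) -> np.ndarray:
        """Evenly spaced interior knots on the scaled [0, 1] range."""
        return np.linspace(0.0, 1.0, n + 1)[:-1]

    def feature_names(self) -> list[str]:
        names: list[str] = []
        av = self.active_variables
        if "l" in self.classes:
            names += [f"lin:{v}" for v in av]
        if "q" in self.classes:
            names += [f"quad:{v}" for v in av]
        if "p" in self.classes:
            for i, a in enumerate(av):
                for b in av[i + 1:]:
                    names.append(f"prod:{a}*{b}")
        if "h" in self.classes:
            for v in av:
                for k in self.knots(self.n_hinge_knots):
                    names.append(f"hinge:{v}@{k:.6f}")
                    names.append(f"rhinge:{v}@{k + 1.0 / self.n_hinge_knots:.6f}")
        if "t" in self.classes:
            for v in av:
                for k in self.knots(self.n_threshold_knots)[1:]:
                    names.append(f"thresh:{v}@{k:.6f}")
        return names

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Design matrix with deterministic column order.

        Hinge features are forward ramps max(0, (s - k) / (1 - k)) and
        reverse ramps max(0, (k' - s) / k') at evenly spaced knots on the
        scaled range; threshold features are indicators s > k.
        """
        s = self._scaled(rows)
        cols: dict[str, np.ndarray] = {}
        av = self.active_variables
        if "l" in self.classes:
            for v in av:
                cols[f"lin:{v}"] = s[v].to_numpy()
        if "q" in self.classes:
            for v in av:
                cols[f"quad:{v}"] = s[v].to_numpy() ** 2
        if "p" in self.classes:
            for i, a in enumerate(av):
                for b in av[i + 1:]:
                    cols[f"prod:{a}*{b}"] = s[a].to_numpy() * s[b].to_numpy()
        if "h" in self.classes:
            for v in av:
                x = s[v].to_numpy()
                for k in self.knots(self.n_hinge_knots):
                    cols[f"hinge:{v}@{k:.6f}"] = np.clip((x - k) / (1.0 - k), 0.0, None)
                    kr = k + 1.0 / self.n_hinge_knots
                    cols[f"rhinge:{v}@{kr:.6f}"] = np.clip((kr - x) / kr, 0.0, None)
        if "t" in self.classes:
            for v in av:
                x = s[v].to_numpy()
                for k in self.knots(self.n_threshold_knots)[1:]:
                    cols[f"thresh:{v}@{k:.6f}"] = (x > k).astype(float)
        return pd.DataFrame(cols, index=rows.index)


def expand_features(rows: pd.DataFrame, spec: FeatureExpansion) -> pd.DataFrame:
    """Design matrix for ``rows`` under a background-fitted expansion."""
    if not spec.minima and spec.active_variables == []:
        raise ValueError("feature expansion has not been fitted on background")
    return spec.transform(rows)


def default_feature_classes(n_presence: int) -> str:
    """Auto feature classes by presence count (MaxEnt convention)."""
    if n_presence < 10:
        return "l"
    if n_presence < 15:
        return "lq"
    if n_presence < 80:
        return "lqh"
    return "lqph"


_BASE_BETA_TABLE = {
    # feature-class group -> (sample sizes, base betas), linearly interpolated
    "lq": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "h": ([0, 1], [0.5, 0.5]),
    "t": ([0, 100], [2.0, 1.0]),
}


def _base_beta(group: str, n: int) -> float:
    xs, ys = _BASE_BETA_TABLE[group]
    return float(np.interp(n, xs, ys))


def _feature_group(name: str) -> str:
    if name.startswith(("hinge:", "rhinge:")):
        return "h"
    if name.startswith("thresh:"):
        return "t"
    return "lq"  # linear, quadratic and product share one table


def regularization_weights(design_presence: pd.DataFrame) -> np.ndarray:
    """Per-feature L1 weights following the published MaxEnt defaults.

    lambda_j = base_beta(class, n) * max(sd_j(presence), 1/sqrt(n)) / sqrt(n),
    with the lower bound guarding features nearly constant at presences.
    """
    n = len(design_presence)
    sd = design_presence.to_numpy().std(axis=0, ddof=1) if n > 1 else np.zeros(design_presence.shape[1])
    floor = 1.0 / np.sqrt(n)
    lam = np.empty(design_presence.shape[1])
    for j, name in enumerate(design_presence.columns):
        lam[j] = _base_beta(_feature_group(name), n) * max(sd[j], floor) / np.sqrt(n)
    return lam


@dataclass
class MaxEntModel:
    """A fitted penalized maximum-entropy model."""

    coefficients: pd.Series  # indexed by feature name
    spec: FeatureExpansion
    reg_multiplier: float
    reg_weights: pd.Series
    log_partition: float  # log Z over the training background
    entropy: float  # H of the fitted background distribution
    meta: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int((self.coefficients.abs() > 0).sum())

    def linear_predictor(self, rows: pd.DataFrame) -> np.ndarray:
        design = expand_features(rows, self.spec)
        return design.to_numpy() @ self.coefficients.to_numpy()

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "coefficients": self.coefficients.to_dict(),
            "reg_multiplier": self.reg_multiplier,
            "reg_weights": self.reg_weights.to_dict(),
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "meta": self.meta,
            "spec": {
                "classes": self.spec.classes,
                "n_hinge_knots": self.spec.n_hinge_knots,
                "n_threshold_knots": self.spec.n_threshold_knots,
                "clamp": self.spec.clamp,
                "minima": self.spec.minima,
                "maxima": self.spec.maxima,
                "variables": self.spec.variables,
                "degenerate": self.spec.degenerate,
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc))
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "MaxEntModel":
        doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        spec = FeatureExpansion(**doc["spec"])
        return cls(
            coefficients=pd.Series(doc["coefficients"]),
            spec=spec,
            reg_multiplier=doc["reg_multiplier"],
            reg_weights=pd.Series(doc["reg_weights"]),
            log_partition=doc["log_partition"],
            entropy=doc["entropy"],
            meta=doc.get("meta", {}),
        )


def fit_maxent(
    presence_rows: pd.DataFrame,
    background_rows: pd.DataFrame,
    spec: FeatureExpansion | None = None,
    reg_multiplier: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
) -> MaxEntModel:
    """Fit the L1-penalized Gibbs model by cyclic coordinate descent.

    Each coordinate takes a proximal Newton step (gradient and curvature of
    the background log-partition, soft-thresholded at its penalty), with the
    background linear predictor updated incrementally. Converged when every
    KKT residual is below ``tol``; raises :class:`ConvergenceError` carrying
    the last gradient norm otherwise.
    """
    if len(presence_rows) < 5:
        raise ValueError("need at least 5 presences to fit")
    if spec is None:
        spec = FeatureExpansion(classes=default_feature_classes(len(presence_rows)))
    if not spec.minima:
        spec.fit(background_rows)

    Fp = expand_features(presence_rows, spec)
    Fb = expand_features(background_rows, spec)
    names = list(Fp.columns)
    Xp, Xb = Fp.to_numpy(), Fb.to_numpy()
    n_p, n_b = Xp.shape[0], Xb.shape[0]
    J = Xp.shape[1]
    mp = Xp.mean(axis=0)
    lam = regularization_weights(Fp) * reg_multiplier

    beta = np.zeros(J)
    eta = np.zeros(n_b)
    kkt = np.inf
    for sweep in range(max_iter):
        max_resid = 0.0
        for j in range(J):
            lz = logsumexp(eta)
            w = np.exp(eta - lz)
            xb = Xb[:, j]
            eb = float(w @ xb)
            g = eb - mp[j]  # gradient of the negative log-likelihood
            h = float(w @ (xb * xb)) - eb * eb
            if beta[j] == 0.0:
                resid = max(abs(g) - lam[j], 0.0)
            else:
                resid = abs(g + lam[j] * np.sign(beta[j]))
            max_resid = max(max_resid, resid)
            if h <= 1e-12:
                continue
            z = h * beta[j] - g
            new = np.sign(z) * max(abs(z) - lam[j], 0.0) / h
            step = np.clip(new - beta[j], -5.0, 5.0)  # guard huge Newton steps
            if step != 0.0:
                beta[j] += step
                eta = eta + step * xb
        kkt = max_resid
        if kkt < tol:
            break
    else:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(KKT residual {kkt:.3e})", gradient_norm=kkt,
        )

    lz = logsumexp(eta)
    raw = np.exp(eta - lz)
    entropy = float(-(raw * np.log(np.clip(raw, 1e-300, None))).sum())
    return MaxEntModel(
        coefficients=pd.Series(beta, index=names),
        spec=spec,
        reg_multiplier=reg_multiplier,
        reg_weights=pd.Series(lam, index=names),
        log_partition=float(lz),
        entropy=entropy,
        meta={
            "n_presence": n_p,
            "n_background": n_b,
            "seed": seed,
            "sweeps": sweep + 1,
            "kkt_residual": kkt,
        },
    )


def predict_suitability(model: MaxEntModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Raw and cloglog suitability for predictor rows.

    raw = exp(beta'f - log Z) (sums to 1 over the training background);
    cloglog = 1 - exp(-exp(H) * raw), a strictly increasing transform of raw
    onto (0, 1), so rankings agree between the two scales.
    """
    eta = model.linear_predictor(rows)
    raw = np.exp(eta - model.log_partition)
    cloglog = 1.0 - np.exp(-np.exp(model.entropy) * raw)
    return pd.DataFrame({"raw": raw, "cloglog": cloglog}, index=rows.index)


def response_curve(model: MaxEntModel, variable: str, rows: pd.DataFrame,
                   n_points: int = 100) -> pd.DataFrame:
    """Marginal response: suitability along one variable, others at their mean."""
    base = rows.mean(numeric_only=True)
    lo, hi = model.spec.minima[variable], model.spec.maxima[variable]
    grid = np.linspace(lo, hi, n_points)
    probe = pd.DataFrame({v: np.full(n_points, base[v]) for v in model.spec.active_variables})
    probe[variable] = grid
    pred = predict_suitability(model, probe)
    return pd.DataFrame({variable: grid, "cloglog": pred["cloglog"].to_numpy()})
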