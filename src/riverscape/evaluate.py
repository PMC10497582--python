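"""Candidate-model evaluation and selection.

Mirrors the kuenm-style model selection procedure: a grid of candidate
models (regularization multiplier x feature-class string) is scored by
partial-ROC significance, omission rate at a chosen error level E, and
small-sample AICc; the best model is the minimum-AICc candidate among the
statistically significant, low-omission ones.

Partial ROC follows the ecological-niche-modelling formulation: the ROC
curve (x = proportion of background predicted suitable, y = sensitivity) is
integrated only over the region where sensitivity >= 1 - E, and the partial
AUC is divided by the random expectation (the same integral of the diagonal)
to give an AUC ratio; 1.0 is random performance, values near 2.0 indicate a
good model. Significance comes from bootstrap resampling of the test
presences: p is the proportion of replicate ratios <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxent import FeatureExpansion, MaxEntModel, fit_maxent, predict_suitability

__all__ = [
    "EvaluationConfig",
    "CandidateModelResult",
    "kfold_split",
    "partial_roc",
    "omission_rate",
    "aicc",
    "select_best",
    "evaluate_candidates",
]


@dataclass
class EvaluationConfig:
    """Knobs for candidate evaluation.

    E is the acceptable omission proportion for both the partial-ROC region
    and the omission filter; defaults follow the pROC literature's
    conventions (E = 0.05, 500 bootstrap iterations resampling 50% of test
    presences, alpha = 0.05, 10-fold cross-validation).
    """

    E: float = 0.05
    iterations: int = 500
    resample_fraction: float = 0.5
    k_folds: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.E < 0.5:
            raise ValueError("E must be in (0, 0.5)")
        if self.iterations < 100:
            raise ValueError("need at least 100 bootstrap iterations")


@dataclass
class CandidateModelResult:
    reg_multiplier: float
    feature_classes: str
    proc_auc_ratio_mean: float
    proc_p_value: float
    omission_rate_E: float
    aicc: float
    n_parameters: int
    delta_aicc: float = float("nan")
    model: MaxEntModel | None = None
    fallback_selected: bool = False


def kfold_split(presence_ids: list | np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded partition of presence ids into k near-equal disjoint folds."""
    ids = np.asarray(presence_ids)
    if len(ids) < k:
        raise ValueError(
            f"only {len(ids)} presences for {k} folds; use k <= {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def _roc_points(pres: np.ndarray, bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step ROC curve over unique score thresholds, from (0,0) to (1,1).

    x = proportion of background with score >= t, y = proportion of test
    presences with score >= t, for t descending over all observed scores.
    """
    thresholds = np.unique(np.concatenate([pres, bg]))[::-1]
    bg_sorted = np.sort(bg)
    pres_sorted = np.sort(pres)
    # count of scores >= t, via binary search on the sorted arrays
    x = 1.0 - np.searchsorted(bg_sorted, thresholds, side="left") / bg.size
    y = 1.0 - np.searchsorted(pres_sorted, thresholds, side="left") / pres.size
    x = np.concatenate([[0.0], x])
    y = np.concatenate([[0.0], y])
    if x[-1] != 1.0 or y[-1] != 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    return x, y


def _pauc_ratio(pres: np.ndarray, bg: np.ndarray, E: float) -> float:
    """Partial AUC ratio over the sensitivity region [1 - E, 1]."""
    x, y = _roc_points(pres, bg)
    ymin = 1.0 - E
    # clip the curve to y >= ymin, interpolating the crossing point in x
    keep_x: list[float] = []
    keep_y: list[float] = []
    for i in range(1, len(x)):
        if y[i] >= ymin:
            if not keep_x:
                if y[i - 1] < ymin and y[i] > y[i - 1]:
                    t = (ymin - y[i - 1]) / (y[i] - y[i - 1])
                    keep_x.append(x[i - 1] + t * (x[i] - x[i - 1]))
                    keep_y.append(ymin)
                else:
                    keep_x.append(x[i - 1])
                    keep_y.append(max(y[i - 1], ymin))
            keep_x.append(x[i])
            keep_y.append(y[i])
    xs = np.asarray(keep_x)
    ys = np.asarray(keep_y)
    if xs.size < 2 or xs[-1] - xs[0] <= 0:
        return 1.0  # degenerate: no area to compare
    auc_model = np.trapezoid(ys, xs)
    auc_random = np.trapezoid(xs, xs)
    if auc_random <= 0:
        return 1.0
    return float(auc_model / auc_random)


def partial_roc(
    scores_at_test_presences: np.ndarray,
    scores_at_background: np.ndarray,
    E: float = 0.05,
    iterations: int = 500,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Bootstrap partial-ROC evaluation.

    Each replicate resamples ``fraction`` of the test presences with
    replacement and computes the partial AUC ratio over sensitivity
    >= 1 - E. Returns (mean ratio, p value, replicate ratios); p is the
    proportion of replicates with ratio <= 1 (performance not better than
    random).
    """
    pres = np.asarray(scores_at_test_presences, dtype=float)
    bg = np.asarray(scores_at_background, dtype=float)
    if pres.size < 10:
        raise ValueError("partial ROC needs at least 10 test presences")
    if np.ptp(pres) == 0 and np.ptp(bg) == 0 and pres[0] == bg[0]:
        warnings.warn("all scores identical: no discrimination, AUC ratio = 1.0",
                      stacklevel=2)
        return 1.0, 1.0, np.ones(iterations)
    rng = np.random.default_rng(seed)
    m = max(1, int(np.ceil(fraction * pres.size)))
    ratios = np.empty(iterations)
    for i in range(iterations):
        sample = pres[rng.integers(0, pres.size, size=m)]
        ratios[i] = _pauc_ratio(sample, bg, E)
    p = float((ratios <= 1.0).mean())
    return float(ratios.mean()), p, ratios


def omission_rate(scores_at_test_presences: np.ndarray, threshold: float) -> float:
    """Proportion of test presences scoring strictly below the threshold."""
    scores = np.asarray(scores_at_test_presences, dtype=float)
    if scores.size == 0:
        raise ValueError("empty test presence set")
    return float((scores < threshold).mean())


def aicc(model: MaxEntModel, presence_rows: pd.DataFrame) -> float:
    """Small-sample AICc of a fitted model at the training presences.

    The likelihood is the Gibbs density normalized to sum to 1 over the
    training background; k counts non-zero coefficients. When n <= k + 1 the
    correction term has no support and the candidate is excluded (+inf).
    """
    n = len(presence_rows)
    k = model.n_parameters
    if n <= k + 1:
        return float("inf")
    eta = model.linear_predictor(presence_rows)
    ll = float(np.sum(eta - model.log_partition))
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_best(
    candidates: list[CandidateModelResult],
    config: EvaluationConfig | None = None,
) -> CandidateModelResult:
    """kuenm-style selection: significant, low-omission, then minimum AICc.

    Filters to proc_p < alpha, then to omission <= E, then takes the lowest
    AICc (ties broken by fewer parameters, then lower multiplier). If no
    significant candidate meets the omission cut, falls back to the
    significant candidate with minimal omission and flags it.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    config = config or EvaluationConfig()
    significant = [c for c in candidates if c.proc_p_value < config.alpha]
    if not significant:
        raise ValueError("no admissible model: no candidate is statistically significant")
    admissible = [c for c in significant if c.omission_rate_E <= config.E]
    fallback = False
    if not admissible:
        min_om = min(c.omission_rate_E for c in significant)
        admissible = [c for c in significant if c.omission_rate_E == min_om]
        fallback = True
    best = min(admissible, key=lambda c: (c.aicc, c.n_parameters, c.reg_multiplier))
    best.fallback_selected = fallback
    finite = [c.aicc for c in candidates if np.isfinite(c.aicc)]
    if finite:
        base = min(finite)
        for c in candidates:
            c.delta_aicc = c.aicc - base
    return best


def evaluate_candidates(
    presence_rows: pd.DataFrame,
    background_rows: pd.DataFrame,
    multipliers: list[float],
    class_strings: list[str],
    config: EvaluationConfig | None = None,
    seed: int = 0,
    n_hinge_knots: int = 50,
) -> list[CandidateModelResult]:
    """Fit and score the full candidate grid.

    For each (multiplier, classes) candidate: AICc and parameter count come
    from the full-data fit; partial ROC and omission rate are averaged over
    seeded k-fold cross-validation, scoring each held-out fold against the
    background with the fold-model's minimum-training-presence threshold,
    on the cloglog scale.
    """
    config = config or EvaluationConfig()
    ids = presence_rows.index.to_numpy()
    folds = kfold_split(ids, k=min(config.k_folds, len(ids)), seed=seed)
    results: list[CandidateModelResult] = []
    for ci, classes in enumerate(class_strings):
        for mi, m in enumerate(multipliers):
            spec_full = FeatureExpansion(classes=classes, n_hinge_knots=n_hinge_knots)
            full = fit_maxent(presence_rows, background_rows, spec_full,
                              reg_multiplier=m, seed=seed)
            ratios, ps, omis = [], [], []
            bg_scores = None
            for fi, test_ids in enumerate(folds):
                train_ids = np.setdiff1d(ids, test_ids)
                spec = FeatureExpansion(classes=classes, n_hinge_knots=n_hinge_knots)
                fold_model = fit_maxent(
                    presence_rows.loc[train_ids], background_rows, spec,
                    reg_multiplier=m, seed=seed,
                )
                test_scores = predict_suitability(fold_model, presence_rows.loc[test_ids])["cloglog"].to_numpy()
                bg_scores = predict_suitability(fold_model, background_rows)["cloglog"].to_numpy()
                train_scores = predict_suitability(fold_model, presence_rows.loc[train_ids])["cloglog"].to_numpy()
                if test_scores.size >= 10:
                    ratio, p, _ = partial_roc(
                        test_scores, bg_scores, E=config.E,
                        iterations=config.iterations,
                        fraction=config.resample_fraction,
                        seed=seed + 1000 * fi + 10 * ci + mi,
                    )
                else:  # tiny folds: pool the fold scores and evaluate once below
                    ratio, p = np.nan, np.nan
                ratios.append(ratio)
                ps.append(p)
                omis.append(omission_rate(test_scores, float(train_scores.min())))
            if np.all(np.isnan(ratios)):
                # folds too small for per-fold pROC: evaluate pooled CV scores
                pooled, pooled_bg = [], []
                for fi, test_ids in enumerate(folds):
                    train_ids = np.setdiff1d(ids, test_ids)
                    spec = FeatureExpansion(classes=classes, n_hinge_knots=n_hinge_knots)
                    fm = fit_maxent(presence_rows.loc[train_ids], background_rows, spec,
                                    reg_multiplier=m, seed=seed)
                    pooled.append(predict_suitability(fm, presence_rows.loc[test_ids])["cloglog"].to_numpy())
                    pooled_bg.append(predict_suitability(fm, background_rows)["cloglog"].to_numpy())
                ratio, p, _ = partial_roc(
                    np.concatenate(pooled), np.mean(pooled_bg, axis=0),
                    E=config.E, iterations=config.iterations,
                    fraction=config.resample_fraction, seed=seed,
                )
                ratios, ps = [ratio], [p]
            results.append(CandidateModelResult(
                reg_multiplier=m,
                feature_classes=classes,
                proc_auc_ratio_mean=float(np.nanmean(ratios)),
                proc_p_value=float(np.nanmean(ps)),
                omission_rate_E=float(np.mean(omis)),
                aicc=aicc(full, presence_rows),
                n_parameters=full.n_parameters,
                model=full,
            ))
    finite = [c.aicc for c in results if np.isfinite(c.aicc)]
    if finite:
        base = min(finite)
        for c in results:
            c.delta_aicc = c.aicc - base
    return results
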