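"""Suitability thresholds, binary habitat maps, and between-species overlap.

Continuous suitability transferred onto a receiving network is binarized
with presence-based thresholds — minimum training presence (MTP: the lowest
suitability at any training presence, zero training omission) or the 10th
percentile of training presences (P10: tolerates 10% of dubious records) —
and the binary maps of a native and an introduced species are compared as
counts and lengths of shared suitable reaches. Elevation distributions of
suitable reach sets are compared with rank tests (Kruskal-Wallis for three
or more groups, Mann-Whitney/Wilcoxon rank-sum for pairs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ElevationGrid
from .network import StreamNetwork

__all__ = [
    "BinaryMap",
    "OverlapSummary",
    "threshold_mtp",
    "threshold_p10",
    "binarize",
    "suitable_length",
    "overlap",
    "union_overlap_percent",
    "elevation_compare",
    "reach_elevations",
]


@dataclass
class BinaryMap:
    """Per-reach suitable/unsuitable flags for one species on one network."""

    suitable: pd.Series  # bool, indexed by reach id
    threshold: float
    rule: str  # "MTP" | "P10"
    species: str = ""
    network_id: str = ""

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())


@dataclass
class OverlapSummary:
    """Pairwise habitat overlap between a native and an introduced species."""

    species_pair: tuple[str, str]
    native_suitable_km: float
    invader_suitable_km: float
    shared_km: float
    native_suitable_n: int
    invader_suitable_n: int
    shared_n: int
    percent_overlap: float  # 100 * shared_n / native_suitable_n
    percent_overlap_km: float  # length-based variant
    flagged: bool = False  # native had zero suitable reaches


def threshold_mtp(training_scores: np.ndarray) -> float:
    """Minimum training presence threshold: training omission is exactly 0."""
    scores = np.asarray(training_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty training scores")
    return float(scores.min())


def threshold_p10(training_scores: np.ndarray) -> float:
    """10-percentile training presence threshold.

    The ceil(0.1 n)-th smallest training score; training omission stays at
    or below 10% plus a tie allowance. Warned below 10 presences, where the
    percentile is poorly determined.
    """
    scores = np.sort(np.asarray(training_scores, dtype=float))
    if scores.size == 0:
        raise ValueError("empty training scores")
    if scores.size < 10:
        warnings.warn("fewer than 10 training presences: P10 threshold is coarse",
                      stacklevel=2)
    k = math.ceil(0.1 * scores.size)
    return float(scores[k - 1])


def binarize(suitability: pd.Series, threshold: float, rule: str,
             species: str = "", network_id: str = "") -> BinaryMap:
    """Suitable iff suitability >= threshold (ties suitable)."""
    return BinaryMap(
        suitable=(suitability >= threshold),
        threshold=float(threshold),
        rule=rule,
        species=species,
        network_id=network_id,
    )


def _lengths(network: StreamNetwork, ids) -> float:
    total = 0.0
    for rid in ids:
        if rid not in network.reaches:
            raise KeyError(f"reach id {rid} not in network")
        total += network.reaches[rid].length_km
    return total


def suitable_length(binary: BinaryMap, network: StreamNetwork) -> float:
    """Total length (km) of suitable reaches."""
    missing = set(binary.suitable.index) - set(network.reaches)
    if missing:
        raise KeyError(f"binary map reach ids not in network: {sorted(missing)[:5]}")
    return _lengths(network, binary.suitable.index[binary.suitable])


def overlap(native: BinaryMap, invader: BinaryMap, network: StreamNetwork) -> OverlapSummary:
    """Habitat overlap: share of native-suitable reaches also invader-suitable.

    The percentage uses the native species' suitable reaches as denominator
    (asymmetric by design); shared length in km is symmetric. A native map
    with zero suitable reaches yields NaN percentages, flagged.
    """
    if not native.suitable.index.equals(invader.suitable.index):
        raise ValueError("binary maps are on different reach sets")
    nat = native.suitable
    inv = invader.suitable
    shared = nat & inv
    nat_km = suitable_length(native, network)
    inv_km = suitable_length(invader, network)
    shared_km = _lengths(network, shared.index[shared])
    n_nat, n_inv, n_shared = int(nat.sum()), int(inv.sum()), int(shared.sum())
    if n_nat == 0:
        warnings.warn("native species has zero suitable reaches: overlap percent undefined",
                      stacklevel=2)
        pct, pct_km, flagged = float("nan"), float("nan"), True
    else:
        pct = 100.0 * n_shared / n_nat
        pct_km = 100.0 * shared_km / nat_km if nat_km > 0 else float("nan")
        flagged = False
    return OverlapSummary(
        species_pair=(native.species, invader.species),
        native_suitable_km=nat_km,
        invader_suitable_km=inv_km,
        shared_km=shared_km,
        native_suitable_n=n_nat,
        invader_suitable_n=n_inv,
        shared_n=n_shared,
        percent_overlap=pct,
        percent_overlap_km=pct_km,
        flagged=flagged,
    )


def union_overlap_percent(native: BinaryMap, invaders: list[BinaryMap]) -> float:
    """Percent of native-suitable reaches suitable for at least one invader."""
    if not invaders:
        raise ValueError("need at least one invader map")
    nat = native.suitable
    any_inv = pd.Series(False, index=nat.index)
    for inv in invaders:
        if not inv.suitable.index.equals(nat.index):
            raise ValueError("binary maps are on different reach sets")
        any_inv |= inv.suitable
    n_nat = int(nat.sum())
    if n_nat == 0:
        return float("nan")
    return 100.0 * int((nat & any_inv).sum()) / n_nat


def reach_elevations(network: StreamNetwork, dem: ElevationGrid,
                     reach_ids) -> np.ndarray:
    """Per-reach elevation: DEM value at the polyline midpoint vertex."""
    out = []
    for rid in reach_ids:
        x, y = network.reaches[rid].midpoint
        out.append(dem.value_at(x, y))
    return np.asarray(out, dtype=float)


def elevation_compare(groups: dict[str, list[int]], network: StreamNetwork,
                      dem: ElevationGrid) -> dict:
    """Rank tests on the elevation distributions of named reach groups.

    Kruskal-Wallis across all groups when there are three or more;
    Mann-Whitney (Wilcoxon rank-sum) for every pair. Reports statistics,
    p-values and group means.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    elev = {}
    for name, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 reaches")
        elev[name] = reach_elevations(network, dem, ids)
    report: dict = {
        "group_means": {name: float(v.mean()) for name, v in elev.items()},
        "group_n": {name: int(v.size) for name, v in elev.items()},
        "pairwise": {},
    }
    names = list(elev)
    if len(names) >= 3:
        allv = np.concatenate(list(elev.values()))
        if np.ptp(allv) == 0:  # scipy rejects the all-identical degenerate case
            report["kruskal_wallis"] = {"statistic": 0.0, "p_value": 1.0}
        else:
            stat, p = stats.kruskal(*elev.values())
            report["kruskal_wallis"] = {"statistic": float(stat), "p_value": float(p)}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.array_equal(np.sort(elev[a]), np.sort(elev[b])):
                report["pairwise"][f"{a}|{b}"] = {"statistic": float("nan"), "p_value": 1.0}
                continue
            stat, p = stats.mannwhitneyu(elev[a], elev[b], alternative="two-sided")
            report["pairwise"][f"{a}|{b}"] = {"statistic": float(stat), "p_value": float(p)}
    return report
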