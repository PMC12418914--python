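"""Dynamic time courses, kidney-mask aggregates and statistics.

Implements the aggregation used for dynamic tracer experiments (mask mean /
SD / sum, fold change relative to baseline, coefficient of variation of a
steady-state segment) and the statistical comparisons: Friedman test across
repeated measures, paired t-test, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TimeCourse",
    "mask_aggregate",
    "fold_change",
    "cov_percent",
    "friedman_compare",
    "paired_ttest",
    "bh_adjust",
]


@dataclass
class TimeCourse:
    """Aggregate value of one metabolite over one mask versus time."""

    times_min: np.ndarray
    values: np.ndarray
    metabolite: str = ""
    mask_name: str = ""
    mode: str = "mean"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.size != self.values.size:
            raise ValueError("times and values length mismatch")
        if self.times_min.size > 1 and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")


def mask_aggregate(
    volume: np.ndarray,
    mask: np.ndarray,
    mode: str = "mean",
    excluded: Optional[np.ndarray] = None,
    voxel_volume_ml: Optional[float] = None,
) -> float:
    """Aggregate a map over the unexcluded voxels of a mask.

    ``mode`` is "mean", "sd" or "sum". NaN voxels and voxels flagged in
    ``excluded`` are dropped. With ``voxel_volume_ml`` given, "sum" is
    volume-weighted (an integral, comparable across grid resolutions).
    """
    mask = np.asarray(mask, dtype=bool)
    sel = mask & np.isfinite(volume)
    if excluded is not None:
        sel &= ~np.asarray(excluded, dtype=bool)
    vals = np.asarray(volume)[sel]
    if mode in ("mean", "sd") and vals.size == 0:
        raise ValueError(f"empty mask for mode {mode!r}")
    if mode == "mean":
        return float(vals.mean())
    if mode == "sd":
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if mode == "sum":
        total = float(vals.sum())
        if voxel_volume_ml is not None:
            total *= voxel_volume_ml
        return total
    raise ValueError(f"unknown aggregation mode {mode!r}")


def fold_change(series: TimeCourse, baseline_index: int = 0) -> TimeCourse:
    """Series divided by its baseline value."""
    baseline = series.values[baseline_index]
    if baseline <= 0:
        raise ValueError("baseline value must be positive")
    return TimeCourse(
        times_min=series.times_min,
        values=series.values / baseline,
        metabolite=series.metabolite,
        mask_name=series.mask_name,
        mode=series.mode,
    )


def cov_percent(values: Sequence[float]) -> float:
    """Coefficient of variation of a segment, percent (sample SD / mean)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 points")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * v.std(ddof=1) / mean)


def friedman_compare(*groups: Sequence[float]) -> Tuple[float, float]:
    """Friedman chi-square test for k related samples (blocks x conditions).

    Each group is one condition measured on the same blocks. Within-block
    ranks use average ranks for ties, with the standard tie correction.
    Identical conditions give statistic 0 and p = 1 exactly.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    data = np.asarray(groups, dtype=float).T  # (n_blocks, k)
    if data.ndim != 2:
        raise ValueError("conditions must have equal block counts")
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    statistic = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)

    # tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = n * k * (k**2 - 1)
    correction = 1.0 - tie_term / denom if denom else 0.0
    if correction <= 0 or statistic <= 0:
        return 0.0, 1.0
    statistic /= correction
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test (scipy backend)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted
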