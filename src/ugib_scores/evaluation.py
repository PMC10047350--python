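"""Discrimination and association analytics for mortality prediction.

ROC curves with the midrank (Mann-Whitney) AUC estimator and DeLong
confidence intervals, Youden-index cutoffs, 2x2 odds ratios with Woolf
logit confidence intervals and Wald tests, Pearson chi-square and Fisher
exact tests, the Mann-Whitney two-sample test, and the Swets qualitative
accuracy bands for AUC values.

Orientation: scores where higher values mean higher risk are evaluated
as-is; lower-is-worse scores (the T-score) are sign-flipped before any
ROC computation, so reported cutoffs stay on the original scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .scores import HIGHER_IS_WORSE, LOWER_IS_WORSE

__all__ = [
    "ContingencyTable2x2",
    "RocCurve",
    "CutoffResult",
    "auc",
    "auc_ci",
    "auc_ci_bootstrap",
    "roc_curve",
    "youden_cutoff",
    "odds_ratio",
    "or_ci_woolf",
    "or_wald_test",
    "chi_square_2x2",
    "fisher_exact",
    "mann_whitney",
    "swets_category",
    "SWETS_LABELS",
]


# ----------------------------------------------------------------------
# 2x2 contingency analytics
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts.

    ``a``/``b`` are deaths/survivors among the exposed group, ``c``/``d``
    deaths/survivors among the unexposed (reference) group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"counts must be non-negative, got {cells}")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def _cells(table: ContingencyTable2x2, haldane: bool) -> tuple[float, float, float, float]:
    # Haldane-Anscombe: +0.5 to every cell, applied only when a zero exists
    if table.has_zero_cell:
        if not haldane:
            raise ValueError(
                "table has a zero cell; pass haldane=True for the +0.5 correction"
            )
        return table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5
    return float(table.a), float(table.b), float(table.c), float(table.d)


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> float:
    """Odds ratio (a*d)/(b*c), optionally Haldane-corrected for zero cells."""
    a, b, c, d = _cells(table, haldane)
    return (a * d) / (b * c)


def _log_or_se(table: ContingencyTable2x2, haldane: bool) -> tuple[float, float]:
    a, b, c, d = _cells(table, haldane)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def or_ci_woolf(
    table: ContingencyTable2x2, alpha: float = 0.05, haldane: bool = False
) -> tuple[float, float]:
    """Woolf (logit) confidence interval for the odds ratio.

    exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)).
    """
    log_or, se = _log_or_se(table, haldane)
    z = stats.norm.ppf(1 - alpha / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def or_wald_test(
    table: ContingencyTable2x2, haldane: bool = False
) -> tuple[float, float]:
    """Wald z test on the log odds ratio; returns (z, two-sided p)."""
    log_or, se = _log_or_se(table, haldane)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return z, p


def chi_square_2x2(
    table: ContingencyTable2x2, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (df = 1), optional Yates correction."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a marginal total is zero")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=continuity)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Fisher exact test, two-sided p (sum of tables at most as probable)."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (midranks) with two-sided p.

    Exact p when both samples are small and untied, otherwise the normal
    approximation with tie correction.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(group_a, group_b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# ROC / AUC
# ----------------------------------------------------------------------


def _oriented(scores, labels, direction) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: need at least one death and one survivor")
    if direction == LOWER_IS_WORSE:
        scores = -scores
    elif direction != HIGHER_IS_WORSE:
        raise ValueError(f"unknown direction {direction!r}")
    return scores, labels


def auc(scores, labels, direction: str = HIGHER_IS_WORSE) -> float:
    """Midrank AUC: the fraction of (death, survivor) pairs in which the
    death scores higher, ties counted one half."""
    s, y = _oriented(scores, labels, direction)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    rank_sum = ranks[y].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong(scores, labels, direction):
    """AUC and DeLong variance via midrank structural components."""
    s, y = _oriented(scores, labels, direction)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - stats.rankdata(neg)) / m
    a = float(v10.mean())
    s10 = float(v10.var(ddof=1)) if m > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def auc_ci(
    scores, labels, direction: str = HIGHER_IS_WORSE, alpha: float = 0.05
) -> tuple[float, float]:
    """DeLong normal-theory confidence interval, truncated to [0, 1].

    Degenerate (zero-variance, e.g. perfect separation) data yields the
    point interval at the AUC itself.
    """
    a, var = _delong(scores, labels, direction)
    if var <= 0:
        return a, a
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var)
    return max(0.0, a - half), min(1.0, a + half)


def auc_ci_bootstrap(
    scores,
    labels,
    direction: str = HIGHER_IS_WORSE,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI; cross-check for the DeLong CI."""
    s, y = _oriented(scores, labels, direction)
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        ranks = stats.rankdata(np.concatenate([bp, bn]))
        aucs[i] = (ranks[: len(bp)].sum() - len(bp) * (len(bp) + 1) / 2) / (
            len(bp) * len(bn)
        )
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RocCurve:
    """Thresholded operating points with AUC and its DeLong interval.

    The classification rule is "score >= threshold predicts death" on the
    oriented (higher-is-worse) scale; thresholds are the distinct observed
    score values on the original scale, bracketed by -inf/+inf sentinels.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    direction: str


def roc_curve(
    scores, labels, direction: str = HIGHER_IS_WORSE, alpha: float = 0.05
) -> RocCurve:
    s, y = _oriented(scores, labels, direction)
    pos, neg = s[y], s[~y]
    uniq = np.unique(s)
    thr_oriented = np.concatenate([[-np.inf], uniq, [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thr_oriented])
    spec = np.array([(neg < t).mean() for t in thr_oriented])
    if direction == LOWER_IS_WORSE:
        thresholds = -thr_oriented
    else:
        thresholds = thr_oriented
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc(scores, labels, direction),
        auc_ci=auc_ci(scores, labels, direction, alpha),
        n_pos=len(pos),
        n_neg=len(neg),
        direction=direction,
    )


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_cutoff(roc: RocCurve) -> CutoffResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the most sensitive (smallest oriented)
    threshold; the infinite sentinels are not eligible cutoffs.
    """
    finite = np.isfinite(roc.thresholds)
    j = roc.sensitivity + roc.specificity - 1.0
    jf = j[finite]
    best = int(np.argmax(jf))  # argmax returns the first (smallest oriented) tie
    thr = roc.thresholds[finite][best]
    return CutoffResult(
        cutoff=float(thr),
        youden_j=float(jf[best]),
        sensitivity=float(roc.sensitivity[finite][best]),
        specificity=float(roc.specificity[finite][best]),
    )


# ----------------------------------------------------------------------
# Swets qualitative accuracy bands
# ----------------------------------------------------------------------

SWETS_LABELS = (
    "non_informative",
    "less_accurate",
    "moderately_accurate",
    "highly_accurate",
    "perfect",
)


def swets_category(auc_value: float) -> str:
    """Qualitative AUC band: 0.5 non-informative, (0.5, 0.7) less accurate,
    [0.7, 0.9) moderately accurate, [0.9, 1) highly accurate, 1 perfect.

    Boundary values are assigned to the better band (an AUC of exactly
    0.7 counts as moderately accurate)."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc_value}")
    if auc_value == 1.0:
        return "perfect"
    if auc_value >= 0.9:
        return "highly_accurate"
    if auc_value >= 0.7:
        return "moderately_accurate"
    if auc_value > 0.5:
        return "less_accurate"
    return "non_informative"
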