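import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from ugib_scores.evaluation import (
    ContingencyTable2x2,
    auc,
    auc_ci,
    auc_ci_bootstrap,
    chi_square_2x2,
    fisher_exact,
    mann_whitney,
    odds_ratio,
    or_ci_woolf,
    or_wald_test,
    roc_curve,
    swets_category,
    youden_cutoff,
)
from ugib_scores.scores import HIGHER_IS_WORSE, LOWER_IS_WORSE


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate all (death, survivor) pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------- AUC


@pytest.mark.parametrize(
    "scores,labels,expected",
    [
        ([4, 5, 1, 2], [1, 1, 0, 0], 1.0),
        ([3, 5, 1, 4], [1, 1, 0, 0], 0.75),
        ([2, 2, 2, 2], [1, 1, 0, 0], 0.5),
    ],
)
def test_auc_examples(scores, labels, expected):
    assert auc(scores, labels) == pytest.approx(expected)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError, match="death and one survivor"):
        auc([1, 2], [1, 1])


@settings(max_examples=200, derandomize=True)
@given(
    n=st.integers(4, 50),
    seed=st.integers(0, 10_000),
)
def test_auc_matches_brute_force_and_sklearn(n, seed):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
    labels = rng.integers(0, 2, size=n).astype(bool)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    got = auc(scores, labels)
    assert got == pytest.approx(brute_force_auc(scores, labels))
    assert got == pytest.approx(roc_auc_score(labels, scores))


@settings(max_examples=100, derandomize=True)
@given(n=st.integers(4, 40), seed=st.integers(0, 10_000))
def test_auc_orientation_flip(n, seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=n)  # continuous: no ties
    labels = rng.integers(0, 2, size=n).astype(bool)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    hi = auc(scores, labels, HIGHER_IS_WORSE)
    lo = auc(scores, labels, LOWER_IS_WORSE)
    assert lo == pytest.approx(1.0 - hi)


def test_delong_ci_degenerate_perfect_separation():
    lo, hi = auc_ci([4, 5, 1, 2], [1, 1, 0, 0])
    assert (lo, hi) == (1.0, 1.0)


def test_delong_ci_brackets_point_estimate():
    scores = [3, 5, 1, 4]
    labels = [1, 1, 0, 0]
    lo, hi = auc_ci(scores, labels)
    assert lo <= auc(scores, labels) <= hi


def test_delong_ci_close_to_bootstrap_on_moderate_sample():
    rng = np.random.default_rng(42)
    labels = np.concatenate([np.ones(60, bool), np.zeros(140, bool)])
    scores = np.where(labels, rng.normal(1.0, 1, 200), rng.normal(0, 1, 200))
    d_lo, d_hi = auc_ci(scores, labels)
    b_lo, b_hi = auc_ci_bootstrap(scores, labels, n_boot=2000, seed=7)
    assert d_lo == pytest.approx(b_lo, abs=0.02)
    assert d_hi == pytest.approx(b_hi, abs=0.02)


# ---------------------------------------------------------------- ROC / Youden


def test_roc_curve_monotone_sensitivity():
    rng = np.random.default_rng(0)
    scores = rng.integers(0, 10, 100).astype(float)
    labels = rng.integers(0, 2, 100).astype(bool)
    roc = roc_curve(scores, labels)
    assert (np.diff(roc.sensitivity) <= 1e-12).all()
    assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]
    assert 0 <= roc.auc <= 1


@pytest.mark.parametrize(
    "pos,neg,cutoff,j",
    [
        ([4, 5], [1, 2], 4, 1.0),
        ([2, 5], [1, 3], 2, 0.5),  # tie at J=0.5: smallest threshold wins
        ([2, 2], [2, 2], 2, 0.0),
    ],
)
def test_youden_cutoff(pos, neg, cutoff, j):
    scores = pos + neg
    labels = [1] * len(pos) + [0] * len(neg)
    cut = youden_cutoff(roc_curve(scores, labels))
    assert cut.cutoff == cutoff
    assert cut.youden_j == pytest.approx(j)


def test_youden_cutoff_on_original_scale_for_lower_is_worse():
    # T-score-like: lower values mean death
    scores = [4, 5, 10, 11]
    labels = [1, 1, 0, 0]
    cut = youden_cutoff(roc_curve(scores, labels, LOWER_IS_WORSE))
    assert cut.youden_j == pytest.approx(1.0)
    assert cut.cutoff in (5, 10)  # any threshold separating the groups


# ---------------------------------------------------------------- odds ratios


def test_or_published_counts():
    assert odds_ratio(ContingencyTable2x2(75, 123, 114, 406)) == pytest.approx(2.1716, abs=1e-4)
    assert odds_ratio(ContingencyTable2x2(18, 5, 11, 25)) == pytest.approx(8.1818, abs=1e-4)
    assert odds_ratio(ContingencyTable2x2(1, 1, 1, 1)) == 1.0


def test_woolf_ci_published_counts():
    lo, hi = or_ci_woolf(ContingencyTable2x2(18, 5, 11, 25))
    assert lo == pytest.approx(2.4192, abs=1e-3)
    assert hi == pytest.approx(27.6707, abs=1e-2)
    _, hi2 = or_ci_woolf(ContingencyTable2x2(75, 123, 121, 1507))
    assert hi2 == pytest.approx(10.6875, abs=1e-3)


def test_woolf_ci_symmetric_on_log_scale_for_unit_or():
    lo, hi = or_ci_woolf(ContingencyTable2x2(1, 1, 1, 1))
    assert lo * hi == pytest.approx(1.0)


@settings(max_examples=100, derandomize=True)
@given(
    a=st.integers(1, 200), b=st.integers(1, 200),
    c=st.integers(1, 200), d=st.integers(1, 200),
)
def test_or_reciprocity_and_ci_bracketing(a, b, c, d):
    t = ContingencyTable2x2(a, b, c, d)
    swapped = ContingencyTable2x2(b, a, d, c)
    assert odds_ratio(t) * odds_ratio(swapped) == pytest.approx(1.0)
    lo, hi = or_ci_woolf(t)
    assert lo <= odds_ratio(t) <= hi
    # scaling all cells up narrows the interval (on the log scale)
    big = ContingencyTable2x2(4 * a, 4 * b, 4 * c, 4 * d)
    blo, bhi = or_ci_woolf(big)
    assert np.log(bhi) - np.log(blo) < np.log(hi) - np.log(lo)


def test_zero_cell_requires_haldane():
    t = ContingencyTable2x2(5, 0, 3, 7)
    with pytest.raises(ValueError, match="zero cell"):
        odds_ratio(t)
    assert odds_ratio(t, haldane=True) > 0


@pytest.mark.parametrize(
    "cells,p",
    [((21, 42, 36, 76), 0.8719), ((39, 47, 36, 76), 0.0586)],
)
def test_wald_p_matches_published(cells, p):
    _, got = or_wald_test(ContingencyTable2x2(*cells))
    assert got == pytest.approx(p, abs=5e-4)


def test_wald_z_zero_for_unit_or():
    z, p = or_wald_test(ContingencyTable2x2(10, 10, 10, 10))
    assert z == 0.0
    assert p == 1.0


# ---------------------------------------------------------------- chi2 / Fisher / MWU


def test_chi_square_hand_value():
    stat, p = chi_square_2x2(ContingencyTable2x2(36, 76, 39, 47))
    assert stat == pytest.approx(3.6055, abs=1e-3)
    assert 0.05 < p < 0.06


def test_chi_square_proportional_table_is_zero():
    stat, p = chi_square_2x2(ContingencyTable2x2(10, 20, 5, 10))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_perfect_association():
    _, p = chi_square_2x2(ContingencyTable2x2(10, 0, 0, 10))
    assert p < 0.001


def test_chi_square_degenerate_marginal():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


def test_fisher_exact_values():
    assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)
    assert fisher_exact(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(2 / 252, rel=1e-6)


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(1 / 3)


def test_mann_whitney_identical_groups():
    vals = list(range(20))
    u, p = mann_whitney(vals, vals)
    assert u == pytest.approx(len(vals) ** 2 / 2)
    assert p > 0.99


def test_mann_whitney_p_decreases_with_shift():
    rng = np.random.default_rng(1)
    base = rng.normal(size=100)
    p_prev = 1.1
    for shift in (0.2, 0.6, 1.2):
        _, p = mann_whitney(base, base + shift)
        assert p < p_prev
        p_prev = p


def test_mann_whitney_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------- Swets bands


@pytest.mark.parametrize(
    "value,label",
    [
        (0.5, "non_informative"),
        (0.45, "non_informative"),
        (0.563, "less_accurate"),
        (0.699, "less_accurate"),
        (0.7, "moderately_accurate"),
        (0.844, "moderately_accurate"),
        (0.9, "highly_accurate"),
        (0.99, "highly_accurate"),
        (1.0, "perfect"),
    ],
)
def test_swets_bands(value, label):
    assert swets_category(value) == label


def test_swets_rejects_out_of_range():
    with pytest.raises(ValueError):
        swets_category(1.2)
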