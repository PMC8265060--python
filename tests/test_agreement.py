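"""Agreement statistics: frozen published/derived values, algebraic
identities, and independent library oracles (scikit-learn, pingouin)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrassess import (
    CrossTab,
    RatingMatrix,
    binary_weights,
    category_agreement,
    cohen_kappa,
    cronbach_alpha,
    crosstab_from_ratings,
    exact_agreement,
    extreme_disagreement,
    interpret_kappa,
    linear_weights,
    quadratic_weights,
    reliability_report,
    wald_interval,
    weight_scheme,
    weighted_kappa,
)
from conftest import generic_scale


def random_crosstab(rng, k=None, max_count=8):
    k = k or int(rng.integers(2, 5))
    counts = rng.integers(0, max_count + 1, size=(k, k))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return CrossTab(generic_scale(k), counts)


# ---------------------------------------------------------------------------
# Exact / per-category agreement (published values)


def test_overall_exact_agreement_matches_published_causality_row(lcat_crosstab):
    est = exact_agreement(lcat_crosstab)
    assert est.point == pytest.approx(80.77, abs=0.005)
    assert est.lower == pytest.approx(65.62, abs=0.005)
    assert est.upper == pytest.approx(95.92, abs=0.005)


@pytest.mark.parametrize("category,cells,ea", [
    ("possible", (7, 1, 3, 15), 84.62),
    ("probable", (6, 4, 0, 16), 84.62),
    ("definite", (5, 0, 1, 20), 96.15),
    ("unlikely", (3, 0, 1, 22), 96.15),
])
def test_per_category_dichotomized_agreement(lcat_crosstab, category, cells, ea):
    got = category_agreement(lcat_crosstab, category)
    assert (got.both_yes, got.rater2_only, got.rater1_only, got.both_no) == cells
    assert got.estimate.point == pytest.approx(ea, abs=0.005)


def test_category_agreement_unknown_category(lcat_crosstab):
    with pytest.raises(KeyError, match="unknown category"):
        category_agreement(lcat_crosstab, "impossible")


def test_category_absent_from_both_raters_is_full_agreement():
    scale = generic_scale(3)
    ct = CrossTab(scale, np.array([[4, 1, 0], [0, 5, 0], [0, 0, 0]]))
    got = category_agreement(ct, "c2")
    assert got.both_no == ct.n and got.estimate.point == 100.0


def test_perfect_and_zero_agreement_bounds_stay_in_range():
    # degenerate proportions collapse the Wald interval at the boundary
    scale = generic_scale(2)
    perfect = exact_agreement(CrossTab(scale, np.diag([5, 5])))
    assert (perfect.point, perfect.lower, perfect.upper) == (100.0, 100.0, 100.0)
    zero = exact_agreement(CrossTab(scale, np.array([[0, 5], [5, 0]])))
    assert (zero.point, zero.lower, zero.upper) == (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Wald intervals (published SEs and bounds)


@pytest.mark.parametrize("successes,se,lo,hi,trunc_hi", [
    (25, 3.77, 88.76, 100.00, True),
    (22, 7.08, 70.75, 98.48, False),
    (24, 5.23, 82.06, 100.00, True),
    (23, 6.27, 76.18, 100.00, True),
])
def test_wald_intervals_match_published_per_category_rows(successes, se, lo, hi, trunc_hi):
    # printed to 2 decimals, occasionally truncated rather than rounded
    est = wald_interval(successes, 26)
    assert est.se == pytest.approx(se, abs=0.01)
    assert est.lower == pytest.approx(lo, abs=0.01)
    assert est.upper == pytest.approx(hi, abs=0.01)
    assert est.truncated_upper is trunc_hi


def test_wald_degenerate_zero_proportion_collapses():
    est = wald_interval(0, 26)
    assert (est.point, est.lower, est.upper) == (0.0, 0.0, 0.0)


def test_wald_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        wald_interval(1, 0)
    with pytest.raises(ValueError):
        wald_interval(5, 4)


# ---------------------------------------------------------------------------
# Kappa


def test_cohen_kappa_from_reconstructed_table(lcat_crosstab):
    # Po = 21/26, Pe = 182/676 -> kappa = 14/19
    res = cohen_kappa(lcat_crosstab)
    assert res.estimate.point == pytest.approx(14 / 19, abs=1e-12)
    assert res.band == "good"
    # Fleiss simplified SE
    po, pe, n = 21 / 26, 182 / 676, 26
    assert res.estimate.se == pytest.approx(math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)), rel=1e-12)


def test_cohen_kappa_against_sklearn_oracle(lcat_crosstab):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rm = lcat_crosstab.expand_to_ratings()
    s = rm.scores()
    expected = sklearn_metrics.cohen_kappa_score(s["rater1"], s["rater2"])
    assert cohen_kappa(lcat_crosstab).estimate.point == pytest.approx(expected, abs=1e-12)


def test_weighted_kappa_linear_matches_abstract_value(lcat_crosstab):
    res = weighted_kappa(lcat_crosstab, linear_weights())
    assert res.estimate.point == pytest.approx(596 / 726, abs=1e-12)
    assert round(res.estimate.point, 2) == 0.82
    assert res.band == "very good"


def test_weighted_kappa_against_sklearn_oracle(lcat_crosstab):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rm = lcat_crosstab.expand_to_ratings()
    s = rm.scores()
    for scheme, wname in [(linear_weights(), "linear"), (quadratic_weights(), "quadratic")]:
        expected = sklearn_metrics.cohen_kappa_score(s["rater1"], s["rater2"], weights=wname)
        got = weighted_kappa(lcat_crosstab, scheme).estimate.point
        assert got == pytest.approx(expected, abs=1e-12)


def test_perfect_diagonal_kappa_is_one_for_every_scheme():
    ct = CrossTab(generic_scale(4), np.diag([2, 3, 4, 5]))
    assert cohen_kappa(ct).estimate.point == pytest.approx(1.0)
    for scheme in (linear_weights(), quadratic_weights(), binary_weights()):
        assert weighted_kappa(ct, scheme).estimate.point == pytest.approx(1.0)


def test_independence_table_kappa_is_zero():
    row = np.array([2, 3, 5])
    col = np.array([4, 4, 2])
    ct = CrossTab(generic_scale(3), np.outer(row, col))  # n * outer of marginals
    assert cohen_kappa(ct).estimate.point == pytest.approx(0.0, abs=1e-12)
    assert weighted_kappa(ct).estimate.point == pytest.approx(0.0, abs=1e-12)


def test_degenerate_marginals_reported_as_undefined():
    ct = CrossTab(generic_scale(2), np.array([[7, 0], [0, 0]]))  # Pe = 1
    res = cohen_kappa(ct)
    assert not res.estimate.defined and "Pe = 1" in res.estimate.note


@settings(derandomize=True, max_examples=150, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_binary_weight_scheme_reduces_to_cohen(seed):
    rng = np.random.default_rng(seed)
    ct = random_crosstab(rng)
    k1 = cohen_kappa(ct).estimate
    k2 = weighted_kappa(ct, binary_weights()).estimate
    assert k1.defined == k2.defined
    if k1.defined:
        assert abs(k1.point - k2.point) <= 1e-12


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_weighted_kappa_invariant_under_score_reflection(seed):
    rng = np.random.default_rng(seed)
    ct = random_crosstab(rng)
    reflected = CrossTab(ct.scale, ct.counts[::-1, ::-1].copy())
    a = weighted_kappa(ct).estimate
    b = weighted_kappa(reflected).estimate
    if a.defined and b.defined:
        assert a.point == pytest.approx(b.point, abs=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1), st.permutations(range(4)))
def test_exact_agreement_invariant_under_joint_relabelling(seed, perm):
    rng = np.random.default_rng(seed)
    ct = random_crosstab(rng, k=4)
    p = list(perm)
    permuted = CrossTab(ct.scale, ct.counts[np.ix_(p, p)].copy())
    assert exact_agreement(ct).point == pytest.approx(exact_agreement(permuted).point)


def test_category_both_yes_counts_sum_to_trace(lcat_crosstab):
    total = sum(
        category_agreement(lcat_crosstab, c).both_yes for c in lcat_crosstab.scale.ids
    )
    assert total == lcat_crosstab.trace == 21


# ---------------------------------------------------------------------------
# Altman bands


@pytest.mark.parametrize("value,band", [
    (0.15, "poor"), (0.20, "poor"), (0.21, "fair"), (0.40, "fair"),
    (0.5, "moderate"), (0.73, "good"), (0.80, "good"), (0.82, "very good"),
    (1.0, "very good"), (-0.3, "poor"),
])
def test_altman_interpretation_bands(value, band):
    assert interpret_kappa(value) == band


def test_kappa_above_one_rejected():
    with pytest.raises(ValueError):
        interpret_kappa(1.01)


# ---------------------------------------------------------------------------
# Cronbach's alpha


def test_alpha_on_reconstructed_pairs_matches_abstract(lcat_ratings):
    est = cronbach_alpha(lcat_ratings)
    assert round(est.point, 2) == 0.95
    # Feldt interval agrees with the published one at printed precision
    assert est.lower == pytest.approx(0.89, abs=0.005)
    assert est.upper == pytest.approx(0.98, abs=0.005)


def test_alpha_against_pingouin_oracle(lcat_ratings):
    pingouin = pytest.importorskip("pingouin")
    expected, _ = pingouin.cronbach_alpha(data=lcat_ratings.scores())
    assert cronbach_alpha(lcat_ratings).point == pytest.approx(expected, abs=1e-9)


def test_alpha_identical_raters_is_one():
    scale = generic_scale(3)
    pairs = [("c0", "c0"), ("c1", "c1"), ("c2", "c2"), ("c0", "c0")]
    rm = RatingMatrix.from_pairs(scale, pairs)
    assert cronbach_alpha(rm).point == pytest.approx(1.0)


def test_alpha_zero_variance_reported_undefined():
    scale = generic_scale(2)
    rm = RatingMatrix.from_pairs(scale, [("c0", "c0"), ("c0", "c0")])
    est = cronbach_alpha(rm)
    assert not est.defined and "variance" in est.note


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_two_rater_alpha_equals_spearman_brown_of_pearson(seed):
    # alpha = 2 rbar / (1 + rbar), exact when the raters' score variances
    # are equal; enforced here by giving rater 2 a permutation of rater 1's
    # scores (same marginal distribution).
    rng = np.random.default_rng(seed)
    k, n = 4, int(rng.integers(4, 40))
    scale = generic_scale(k)
    ids = scale.ids
    r1 = [ids[rng.integers(k)] for _ in range(n)]
    r2 = [r1[i] for i in rng.permutation(n)]
    rm = RatingMatrix.from_pairs(scale, list(zip(r1, r2)))
    s = rm.scores().to_numpy(dtype=float)
    if s.sum(axis=1).var() == 0 or s[:, 0].std() == 0:
        return
    r = np.corrcoef(s[:, 0], s[:, 1])[0, 1]
    if r <= -1 + 1e-12:
        return
    assert cronbach_alpha(rm).point == pytest.approx(2 * r / (1 + r), abs=1e-10)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_two_rater_alpha_equals_stepped_up_consistency_icc(seed):
    # general identity: alpha = 1 - MSE/MSB = 2 rho / (1 + rho) with rho the
    # consistency intraclass correlation (MSB - MSE)/(MSB + MSE), computed
    # here independently from the two-way ANOVA mean squares
    rng = np.random.default_rng(seed)
    k, n = 4, int(rng.integers(4, 40))
    scale = generic_scale(k)
    ids = scale.ids
    pairs = [(ids[rng.integers(k)], ids[rng.integers(k)]) for _ in range(n)]
    rm = RatingMatrix.from_pairs(scale, pairs)
    s = rm.scores().to_numpy(dtype=float)
    if s.sum(axis=1).var() == 0:
        return
    row_means = s.mean(axis=1)
    col_means = s.mean(axis=0)
    grand = s.mean()
    msb = 2 * ((row_means - grand) ** 2).sum() / (n - 1)
    sse = ((s - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / (n - 1)
    rho = (msb - mse) / (msb + mse)
    assert cronbach_alpha(rm).point == pytest.approx(2 * rho / (1 + rho), abs=1e-10)


# ---------------------------------------------------------------------------
# Extreme disagreement


def test_no_extreme_disagreement_in_reconstructed_causality_data(lcat_ratings):
    est = extreme_disagreement(lcat_ratings)
    assert (est.point, est.lower, est.upper) == (0.0, 0.0, 0.0)


def test_single_extreme_pair_matches_published_avoidability_row():
    scale = generic_scale(4)
    pairs = [("c0", "c3")] + [("c1", "c1")] * 25  # one 0-vs-3 split among 26
    rm = RatingMatrix.from_pairs(scale, pairs)
    est = extreme_disagreement(rm)
    assert est.point == pytest.approx(3.85, abs=0.005)
    assert est.lower == 0.0 and est.truncated_lower
    assert est.upper == pytest.approx(11.24, abs=0.005)


def test_threshold_zero_is_complement_of_exact_agreement(lcat_ratings):
    est = extreme_disagreement(lcat_ratings, threshold=0)
    ea = exact_agreement(crosstab_from_ratings(lcat_ratings))
    assert est.point == pytest.approx(100 - ea.point)


def test_extreme_disagreement_requires_two_raters():
    scale = generic_scale(2)
    df = pd.DataFrame(
        {"r1": ["c0", "c1"], "r2": ["c0", "c1"], "r3": ["c1", "c1"]}, index=["a", "b"]
    )
    rm = RatingMatrix(scale, df)
    with pytest.raises(ValueError, match="exactly 2 raters"):
        extreme_disagreement(rm)


# ---------------------------------------------------------------------------
# Report assembly


def test_reliability_report_assembles_all_components(lcat_ratings):
    rep = reliability_report(lcat_ratings)
    assert rep.tool_id == "LCAT" and rep.n == 26
    assert set(rep.categories) == {"unlikely", "possible", "probable", "definite"}
    assert sum(c.both_yes for c in rep.categories.values()) == 21
    d = rep.to_dict()
    assert d["weighted_kappa"]["scheme"] == "linear"
    assert d["extreme_disagreement"]["threshold"] == 2


def test_single_case_report_has_degenerate_flags():
    scale = generic_scale(4)
    rm = RatingMatrix.from_pairs(scale, [("c3", "c3")])
    rep = reliability_report(rm)
    assert rep.exact_agreement.point == 100.0
    assert not rep.cronbach_alpha.defined
    assert not rep.cohen_kappa.estimate.defined  # Pe = 1 with a single cell


def test_weight_scheme_lookup():
    assert weight_scheme("linear").name == "linear"
    with pytest.raises(ValueError, match="unknown weight scheme"):
        weight_scheme("cubic")
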