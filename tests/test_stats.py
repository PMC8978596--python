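"""Statistical-comparison tests: exact Mann-Whitney U, Hedges' g,
normality routing, group comparison and paired stress tests."""

import numpy as np
import pytest
from scipy import stats as sps

from evprofiler.stats import (compare_groups, exact_mwu, hedges_g,
                              hedges_g_from_summary, normality_route,
                              paired_change_test, shapiro_p)

from oracles import enumerate_mwu_p, enumerate_signed_rank_p


# ---------------------------------------------------------------------------
# exact Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mwu_two_vs_two_textbook_case():
    res = exact_mwu([1.0, 2.0], [3.0, 4.0])
    assert res.u == 0.0
    assert res.p == pytest.approx(1 / 3)   # 2 * (1/6) over the 6 labelings
    assert res.method == "exact"


def test_mwu_identical_samples_p_near_one():
    rng = np.random.default_rng(4)
    x = rng.normal(size=8)
    jitter = rng.normal(0, 1e-9, 8)  # break ties without moving ranks systematically
    res = exact_mwu(x, x + jitter)
    assert res.u == pytest.approx(len(x) ** 2 / 2, abs=4)
    assert res.p > 0.5


def test_mwu_matches_full_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(60):
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 7))
        x1, x2 = rng.normal(size=n1), rng.normal(size=n2)
        res = exact_mwu(x1, x2)
        assert res.p == pytest.approx(enumerate_mwu_p(x1, x2), abs=1e-12)


def test_mwu_matches_scipy_exact():
    rng = np.random.default_rng(13)
    for _ in range(40):
        x1, x2 = rng.normal(size=6), rng.normal(size=8)
        res = exact_mwu(x1, x2)
        ref = sps.mannwhitneyu(x1, x2, method="exact", alternative="two-sided")
        assert res.u == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mwu_complementarity():
    rng = np.random.default_rng(14)
    for _ in range(20):
        x1, x2 = rng.normal(size=5), rng.normal(size=7)
        u12 = exact_mwu(x1, x2).u
        u21 = exact_mwu(x2, x1).u
        assert u12 + u21 == pytest.approx(len(x1) * len(x2))


def test_mwu_ties_use_exact_permutation_and_match_enumeration():
    x1 = [1.0, 2.0, 2.0, 5.0]
    x2 = [2.0, 3.0, 4.0]
    res = exact_mwu(x1, x2)
    assert res.has_ties and res.method == "exact_permutation"
    assert res.p == pytest.approx(enumerate_mwu_p(x1, x2), abs=1e-12)


def test_mwu_rejects_empty_group():
    with pytest.raises(ValueError):
        exact_mwu([], [1.0])


# ---------------------------------------------------------------------------
# Hedges' g
# ---------------------------------------------------------------------------

def test_hedges_g_height_worked_example():
    """Standardized group difference in stature: 181.13 +/- 5.76 vs
    174.05 +/- 6.67 (n = 10 + 10) gives g = 1.09."""
    es = hedges_g_from_summary(181.13, 5.76, 10, 174.05, 6.67, 10)
    assert round(es.g, 2) == 1.09
    assert es.ci_low < es.g < es.ci_high
    # normal-approximation CI lands near the reported interval
    assert es.ci_low == pytest.approx(0.15, abs=0.05)
    assert es.ci_high == pytest.approx(2.03, abs=0.05)


def test_hedges_g_zero_for_equal_means():
    assert hedges_g_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10).g == 0.0


def test_hedges_g_antisymmetry():
    rng = np.random.default_rng(5)
    x1, x2 = rng.normal(1, 1, 12), rng.normal(0, 1, 9)
    a, b = hedges_g(x1, x2), hedges_g(x2, x1)
    assert a.g == pytest.approx(-b.g)
    assert a.ci_low == pytest.approx(-b.ci_high)
    assert a.ci_high == pytest.approx(-b.ci_low)


def test_hedges_g_affine_invariance():
    rng = np.random.default_rng(6)
    x1, x2 = rng.normal(3, 2, 10), rng.normal(1, 2, 10)
    base = hedges_g(x1, x2)
    scaled = hedges_g(5 * x1 - 7, 5 * x2 - 7)
    assert scaled.g == pytest.approx(base.g, rel=1e-12)


def test_hedges_g_sign_matches_mean_difference():
    rng = np.random.default_rng(7)
    for _ in range(20):
        x1, x2 = rng.normal(size=8), rng.normal(size=8)
        g = hedges_g(x1, x2).g
        assert np.sign(g) == np.sign(x1.mean() - x2.mean())


def test_hedges_g_rejects_degenerate_input():
    with pytest.raises(ValueError):
        hedges_g_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)
    with pytest.raises(ValueError):
        hedges_g_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)


# ---------------------------------------------------------------------------
# normality routing
# ---------------------------------------------------------------------------

def test_route_normal_data_to_t():
    rng = np.random.default_rng(8)
    assert normality_route(rng.normal(size=10), rng.normal(size=10)) == "student_t"


def test_route_skewed_data_to_mwu_in_majority_of_seeds():
    chosen = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        x_high = np.exp(rng.normal(0, 1.5, 10))  # heavy right skew
        x_low = rng.normal(size=10)
        if normality_route(x_high, x_low) == "mann_whitney_exact":
            chosen += 1
    assert chosen > 120


def test_route_constant_group_falls_back_nonparametric():
    assert normality_route(np.ones(10), np.random.default_rng(0).normal(size=10)) \
        == "mann_whitney_exact"
    assert shapiro_p(np.ones(5)) is None


def test_route_agrees_with_reference_shapiro():
    rng = np.random.default_rng(9)
    x1, x2 = rng.normal(size=10), rng.normal(size=10)
    expected = ("student_t"
                if min(sps.shapiro(x1).pvalue, sps.shapiro(x2).pvalue) >= 0.05
                else "mann_whitney_exact")
    assert normality_route(x1, x2) == expected


# ---------------------------------------------------------------------------
# compare_groups
# ---------------------------------------------------------------------------

def test_compare_groups_attaches_g_only_when_significant_parametric():
    rng = np.random.default_rng(10)
    strong = compare_groups(rng.normal(5, 1, 10), rng.normal(0, 1, 10))
    assert strong.test == "student_t" and strong.p < 0.05
    assert strong.effect is not None
    assert "mean" in strong.summaries["high"]

    null = compare_groups(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
    if null.test == "student_t" and null.p >= 0.05:
        assert null.effect is None


def test_compare_groups_nonparametric_reports_median_iqr():
    rng = np.random.default_rng(11)
    x_high = np.exp(rng.normal(0, 2, 10))
    x_low = np.exp(rng.normal(0, 2, 10))
    cmp_ = compare_groups(x_high, x_low)
    if cmp_.test == "mann_whitney_exact":
        assert "median" in cmp_.summaries["high"]
        assert "iqr" in cmp_.summaries["low"]
        assert cmp_.effect is None


def test_compare_groups_degenerate_constant_input():
    cmp_ = compare_groups(np.ones(5), np.ones(5))
    assert cmp_.degenerate and cmp_.p == 1.0


def test_compare_groups_type_one_error_short_sweep():
    """Nominal alpha on identically distributed groups (400 seeds; the
    1000-seed version runs in the acceptance suite)."""
    hits = 0
    for seed in range(400):
        rng = np.random.default_rng(30_000 + seed)
        if compare_groups(rng.normal(size=10), rng.normal(size=10)).p < 0.05:
            hits += 1
    assert 0.02 <= hits / 400 <= 0.08


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def test_paired_no_change_is_degenerate_p_one():
    pre = np.arange(1.0, 9.0)
    res = paired_change_test(pre, pre)
    assert res.degenerate and res.p == 1.0


def test_paired_signed_rank_matches_sign_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(30):
        d = rng.normal(size=5)
        pre = rng.normal(size=5)
        res_exp = enumerate_signed_rank_p(d)
        from evprofiler.stats import _signed_rank_exact_p
        _, p = _signed_rank_exact_p(d)
        assert p == pytest.approx(res_exp, abs=1e-12)
        del pre


def test_paired_signed_rank_matches_scipy_exact():
    rng = np.random.default_rng(13)
    from evprofiler.stats import _signed_rank_exact_p
    for _ in range(30):
        d = rng.normal(size=8)
        _, p = _signed_rank_exact_p(d)
        ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_paired_igf1_decline_detected_in_most_seeds():
    """A -13.5% implanted decline in IGF-I is detected (p < 0.05) in the
    majority of 25 simulated cohorts of n = 20."""
    from evprofiler.synthetic import generate_biomarkers
    hits = 0
    for seed in range(25):
        rng = np.random.default_rng(40_000 + seed)
        subs = [(f"H{i}", "high") for i in range(10)] + \
               [(f"L{i}", "low") for i in range(10)]
        bm = generate_biomarkers(subs, rng)
        sub = bm[bm.analyte == "IGF-I"].pivot(index="subject_id",
                                              columns="timepoint", values="value")
        res = paired_change_test(sub["D0"].to_numpy(), sub["D3"].to_numpy())
        hits += res.p < 0.05
    assert hits >= 13


def test_paired_requires_equal_length_and_minimum_n():
    with pytest.raises(ValueError):
        paired_change_test([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        paired_change_test([1.0, 2.0], [2.0, 3.0])
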