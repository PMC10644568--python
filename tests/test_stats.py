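import math

import numpy as np
import pytest

from etmpheno import (
    comparison_matrix,
    fisher_combined,
    group_summary,
    independence_map,
    normality_gate,
    pearson_r2,
    pooled_t,
    shapiro_wilk,
    significance_category,
    welch_t,
)
from etmpheno.cohort import GROUPS, MODALITIES


def chi2_sf_even_df(x: float, m: int) -> float:
    """Independent closed-form survival function of chi2 with 2m df:
    P(X > x) = exp(-x/2) * sum_{k<m} (x/2)^k / k!   (integration by parts)."""
    h = x / 2.0
    return math.exp(-h) * sum(h**k / math.factorial(k) for k in range(m))


# ----------------------------------------------------------------- summaries

def test_group_summary_reproduces_published_impedance_means(fixture_cohort):
    s_an = group_summary(fixture_cohort.values("Z", "AN"), "AN", "Z")
    assert s_an.mean == pytest.approx(22206.2, abs=0.05)
    assert s_an.sem == pytest.approx(3400.7, abs=0.05)
    s_ca = group_summary(fixture_cohort.values("Z", "CA"), "CA", "Z")
    assert s_ca.mean == pytest.approx(110018.8, abs=0.05)
    assert s_ca.sem == pytest.approx(20293.8, abs=0.05)


def test_sem_uses_population_sd_convention(fixture_cohort):
    """The sample-SD convention (ddof=1) would give 3529, not the published
    3400.7 — this pins the divisor-n convention."""
    v = fixture_cohort.values("Z", "AN")
    sample_sem = v.std(ddof=1) / np.sqrt(v.size)
    assert sample_sem == pytest.approx(3529, abs=1)
    assert group_summary(v, "AN", "Z").sem == pytest.approx(3400.7, abs=0.05)


def test_group_summary_single_value():
    s = group_summary([3.2], "AN", "Z")
    assert (s.mean, s.sem, s.n) == (3.2, 0.0, 1)


def test_group_summary_empty_input():
    with pytest.raises(ValueError):
        group_summary([], "AN", "Z")


# ----------------------------------------------------------------- normality

def test_all_fixture_vectors_pass_normality(fixture_cohort):
    for g in GROUPS:
        for m in MODALITIES:
            _, p = shapiro_wilk(fixture_cohort.values(m, g))
            assert p > 0.05, (g, m)


def test_shapiro_preconditions():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError, match="constant"):
        shapiro_wilk([2.0, 2.0, 2.0, 2.0])


def test_normality_gate_is_warn_only(fixture_cohort):
    frame = normality_gate(fixture_cohort)
    assert len(frame) == 12
    assert frame["normal"].all()


# ----------------------------------------------------------------- t-tests

def test_welch_reproduces_published_single_modality_p(fixture_cohort):
    p = welch_t(fixture_cohort.values("Z", "AN"), fixture_cohort.values("Z", "CA"))
    assert p == pytest.approx(2.6e-3, rel=0.02)
    p = welch_t(fixture_cohort.values("K", "AN"), fixture_cohort.values("K", "CA"))
    assert p == pytest.approx(7.64e-8, rel=0.005)


def test_pooled_t_reproduces_published_relaxation_row(fixture_cohort):
    """The published %R comparisons match the pooled-variance Student t,
    not Welch — the discovered convention of the source analysis."""
    a = fixture_cohort.values("%R", "AN")
    fa = fixture_cohort.values("%R", "FA")
    ca = fixture_cohort.values("%R", "CA")
    assert pooled_t(a, fa) == pytest.approx(2.3e-4, rel=0.02)
    assert pooled_t(a, ca) == pytest.approx(2.2e-3, rel=0.05)
    assert pooled_t(fa, ca) == pytest.approx(7.9e-2, rel=0.02)
    # and Welch demonstrably does not reproduce that row
    assert welch_t(a, fa) > 1e-2


def test_identical_samples_give_p_one():
    a = [1.0, 2.0, 3.0]
    assert welch_t(a, a) == pytest.approx(1.0)


def test_t_test_needs_two_per_group():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


# ----------------------------------------------------------------- R-square

def test_r2_exact_line():
    x = np.arange(10.0)
    assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)


def test_r2_symmetry(fixture_cohort):
    x = fixture_cohort.values("k", "AN")
    y = fixture_cohort.values("%R", "AN")
    assert pearson_r2(x, y) == pytest.approx(pearson_r2(y, x))


def test_r2_degenerate_inputs():
    with pytest.raises(ValueError):
        pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_r2([1.0, 2.0], [1.0, 2.0])


def test_independence_map_reproduces_published_mechanical_pair(fixture_cohort):
    im = independence_map(fixture_cohort)
    assert len(im) == 18
    assert im.r2(("k", "%R"), "AN") == pytest.approx(0.48, abs=0.01)
    assert im.r2(("k", "%R"), "FA") == pytest.approx(0.63, abs=0.01)
    assert im.r2(("k", "%R"), "CA") == pytest.approx(0.008, abs=0.002)
    assert all(0.0 <= v <= 1.0 for v in im.entries.values())


# ----------------------------------------------------------------- Fisher

def test_fisher_single_p_is_identity():
    for p in (0.5, 0.01, 1e-6):
        assert fisher_combined([p]) == pytest.approx(p, rel=1e-9)


def test_fisher_all_ones():
    assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_fisher_against_closed_form_oracle():
    """Combination of the four published AN-vs-CA single-modality p-values,
    checked against an independent closed-form chi-square survival sum."""
    ps = [2.6e-3, 7.64e-8, 1.4e-4, 2.2e-3]
    x2 = -2 * sum(math.log(p) for p in ps)
    expected = chi2_sf_even_df(x2, len(ps))
    got = fisher_combined(ps)
    assert got == pytest.approx(expected, rel=1e-9)
    assert got == pytest.approx(5.8e-13, rel=0.01)


def test_fisher_rejects_invalid_p():
    with pytest.raises(ValueError):
        fisher_combined([0.0, 0.5])
    with pytest.raises(ValueError):
        fisher_combined([])


# ----------------------------------------------------------------- matrix

def test_comparison_matrix_shape_and_spots(fixture_cohort):
    cm = comparison_matrix(fixture_cohort)
    assert len(cm) == 45
    allfour = ("Z", "K", "k", "%R")
    assert cm.p(allfour, ("AN", "CA")) == pytest.approx(5.76e-13, rel=0.05)
    assert cm.p(allfour, ("FA", "CA")) == pytest.approx(4.5e-3, rel=0.05)
    assert cm.category(allfour, ("AN", "CA")) == "***"
    assert cm.category(("Z",), ("AN", "FA")) == "ns"


def test_comparison_matrix_welch_convention_differs(fixture_cohort):
    cm_pub = comparison_matrix(fixture_cohort, convention="published")
    cm_welch = comparison_matrix(fixture_cohort, convention="welch")
    assert cm_pub.p(("Z",), ("AN", "CA")) == cm_welch.p(("Z",), ("AN", "CA"))
    assert cm_pub.p(("%R",), ("AN", "FA")) != cm_welch.p(("%R",), ("AN", "FA"))
    with pytest.raises(ValueError):
        comparison_matrix(fixture_cohort, convention="bogus")


def test_adding_modality_grows_combined_statistic(fixture_cohort):
    """-2 sum(ln p) can only grow when another modality (p < 1) joins."""
    cm = comparison_matrix(fixture_cohort)

    def x2(subset, pair):
        # invert the chi-square mapping per subset size is awkward; recompute
        ps = [cm.p((m,), pair) for m in subset]
        return -2 * np.sum(np.log(ps))

    for pair in (("AN", "FA"), ("AN", "CA"), ("FA", "CA")):
        assert x2(("Z", "K"), pair) >= x2(("Z",), pair)
        assert x2(("Z", "K", "k", "%R"), pair) >= x2(("Z", "K", "k"), pair)


def test_significance_star_boundaries():
    assert significance_category(0.5) == "ns"
    assert significance_category(0.05) == "ns"
    assert significance_category(0.049) == "*"
    assert significance_category(0.009) == "**"
    assert significance_category(0.0009) == "***"
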