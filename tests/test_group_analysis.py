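"""Group statistics: effect sizes, odds ratios, FDR, regressions, subgroups."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stx

from npnorm import (
    SimConfig,
    bh_adjust,
    cohens_d,
    demographic_regression,
    fisher_exact_2x2,
    generate_cohort,
    odds_ratio,
    score_dataframe,
    subgroup_compare,
)
from npnorm.published import TSCORE_SUMMARY, TEST_ROWS, SUMMARY_ROWS


# ---------------------------------------------------------------- Cohen's d

def test_cohens_d_reproduces_published_case_control_value():
    s = TSCORE_SUMMARY["gp_dh"]
    r = cohens_d(s["mean"][0], s["sd"][0], s["n"][0],
                 s["mean"][1], s["sd"][1], s["n"][1])
    assert round(r.estimate, 2) == -0.18


def test_cohens_d_zero_for_equal_means():
    r = cohens_d(10, 2, 50, 10, 3, 60)
    assert r.estimate == 0.0


def test_cohens_d_unit_effect_with_normal_ci():
    r = cohens_d(0, 1, 100, 1, 1, 100)
    assert r.estimate == pytest.approx(1.0)
    se = math.sqrt(1 / 100 + 1 / 100 + 1 / (2 * 200))
    assert r.ci_low == pytest.approx(1 - 1.959963984540054 * se)
    assert r.ci_high == pytest.approx(1 + 1.959963984540054 * se)


def test_cohens_d_rejects_degenerate_variance():
    with pytest.raises(ValueError):
        cohens_d(1, 0.0, 30, 2, 1.0, 30)


def test_noncentral_t_ci_close_to_normal_approx():
    a = cohens_d(0, 1, 150, 0.4, 1, 150)
    b = cohens_d(0, 1, 150, 0.4, 1, 150, noncentral_ci=True)
    assert a.ci_low == pytest.approx(b.ci_low, abs=0.01)
    assert a.ci_high == pytest.approx(b.ci_high, abs=0.01)


# -------------------------------------------------------------- odds ratios

def test_odds_ratio_equal_proportions_is_one():
    r = odds_ratio(10, 100, 20, 200)
    assert r.estimate == pytest.approx(1.0)


def test_odds_ratio_all_cells_one():
    r = odds_ratio(1, 2, 1, 2)
    assert r.estimate == pytest.approx(1.0)
    # CI symmetric on the log scale around log OR = 0
    assert math.log(r.ci_low) == pytest.approx(-math.log(r.ci_high))


def test_odds_ratio_zero_cell_needs_continuity():
    with pytest.raises(ValueError, match="continuity"):
        odds_ratio(0, 50, 5, 50)
    r = odds_ratio(0, 50, 5, 50, continuity=True)
    assert r.estimate > 1


@settings(deadline=None, max_examples=100, derandomize=True)
@given(stx.tuples(*[stx.integers(min_value=1, max_value=200)] * 4))
def test_odds_ratio_label_swap_reciprocity(cells):
    a, b, c, d = cells
    i1, t1, i2, t2 = a, a + b, c, c + d
    r = odds_ratio(i1, t1, i2, t2)
    s = odds_ratio(i2, t2, i1, t1)
    assert s.estimate == pytest.approx(1 / r.estimate)
    assert s.ci_low == pytest.approx(1 / r.ci_high)
    assert s.ci_high == pytest.approx(1 / r.ci_low)


# ----------------------------------------------------------------- BH / FDR

def bh_brute_force(ps):
    """Independent step-up oracle straight from the definition."""
    k = len(ps)
    order = sorted(range(k), key=lambda i: ps[i])
    adj = [None] * k
    for rank_pos, i in enumerate(order, start=1):
        adj[i] = min(
            min(ps[order[j - 1]] * k / j for j in range(rank_pos, k + 1)), 1.0
        )
    return adj


def test_bh_reproduces_published_adjusted_p():
    raw8 = [TSCORE_SUMMARY[t]["p"] for t in TEST_ROWS]
    assert [round(p, 3) for p in bh_adjust(raw8, k=8)] == [
        0.036, 0.251, 0.008, 0.745, 0.266, 0.036, 0.036, 0.134
    ]
    raw2 = [TSCORE_SUMMARY[t]["p"] for t in SUMMARY_ROWS]
    assert [round(p, 3) for p in bh_adjust(raw2, k=2)] == [0.050, 0.012]


def test_bh_single_p_unchanged():
    assert bh_adjust([0.123]) == [0.123]


def test_bh_validates_inputs():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 0.2], k=3)


@settings(deadline=None, max_examples=300, derandomize=True)
@given(stx.lists(stx.floats(min_value=0, max_value=1), min_size=1, max_size=20))
def test_bh_equals_brute_force_oracle(ps):
    got = bh_adjust(ps)
    want = bh_brute_force(ps)
    assert got == pytest.approx(want, abs=1e-12)
    # order preserving and never below raw p
    for g, p in zip(got, ps):
        assert g >= p - 1e-15


# ------------------------------------------------------------- regressions

def test_ttest_p_equals_group_indicator_regression_p():
    import scipy.stats as st
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    x1, x2 = rng.normal(0, 1, 80), rng.normal(0.5, 1, 70)
    t_p = st.ttest_ind(x1, x2, equal_var=True).pvalue
    y = np.concatenate([x1, x2])
    g = np.concatenate([np.zeros(80), np.ones(70)])
    reg_p = sm.OLS(y, sm.add_constant(g)).fit().pvalues[1]
    assert t_p == pytest.approx(reg_p, rel=1e-10)
    # and the summary-statistic route used by cohens_d agrees too
    r = cohens_d(x1.mean(), x1.std(ddof=1), 80, x2.mean(), x2.std(ddof=1), 70)
    assert r.p == pytest.approx(t_p, rel=1e-10)


def test_demographic_regression_recovers_male_advantage():
    rng = np.random.default_rng(17)
    n = 320
    male = rng.integers(0, 2, n)
    age = rng.integers(18, 65, n)
    edu = rng.integers(0, 22, n)
    t = 50 + 3 * male + rng.normal(0, 9, n)
    res = demographic_regression(t, age, edu, male)
    uni = {r.label: r for r in res}
    r = uni["uni:male"]
    assert r.ci_low <= 3 <= r.ci_high
    m = uni["multi:male"]
    assert m.ci_low <= 3 <= m.ci_high


def test_permuted_covariate_ci_covers_zero():
    rng = np.random.default_rng(21)
    n = 300
    covered = 0
    reps = 60
    for _ in range(reps):
        age = rng.integers(18, 65, n)
        t = 50 + 0.2 * age + rng.normal(0, 8, n)
        perm = rng.permutation(age)
        res = demographic_regression(t, perm, rng.integers(0, 22, n),
                                     rng.integers(0, 2, n), multivariable=False)
        r = {x.label: x for x in res}["uni:age"]
        covered += r.ci_low <= 0 <= r.ci_high
    assert covered / reps >= 0.90


def test_zero_noise_regression_is_exact():
    n = 100
    rng = np.random.default_rng(2)
    age = rng.integers(18, 65, n).astype(float)
    edu = rng.integers(0, 22, n).astype(float)
    male = rng.integers(0, 2, n).astype(float)
    t = 40 + 0.5 * age - 0.3 * edu + 2 * male
    res = demographic_regression(t, age, edu, male)
    multi = {r.label: r.estimate for r in res if r.label.startswith("multi")}
    assert multi["multi:age"] == pytest.approx(0.5, abs=1e-8)
    assert multi["multi:edu"] == pytest.approx(-0.3, abs=1e-8)
    assert multi["multi:male"] == pytest.approx(2.0, abs=1e-8)


def test_fisher_exact_two_sided():
    orr, p = fisher_exact_2x2(8, 2, 1, 5)
    import scipy.stats as st
    orr2, p2 = st.fisher_exact([[8, 2], [1, 5]])
    assert (orr, p) == (orr2, p2)


# ---------------------------------------------------------------- subgroups

def _scored_cohort(cfg):
    return score_dataframe(generate_cohort(cfg))


def test_subgroup_art_effect_recovered():
    """An injected on-ART advantage of d = 0.30 per test is recovered by
    the ART subgroup contrast (the generator is the oracle)."""
    from dataclasses import replace
    cfg = replace(SimConfig(), art_effect_d=0.30, cd4_effect_d=0.0)
    ds = []
    for i in range(25):
        scored = _scored_cohort(replace(cfg, seed=100 + i))
        res = {r.label: r for r in subgroup_compare(scored, "art")}
        ds.append(res["art:wais_ds"].estimate)
    assert np.mean(ds) == pytest.approx(0.30, abs=0.08)


def test_null_cohort_yields_no_fdr_discoveries():
    """With identical subgroups the per-test family produces no
    BH-adjusted discovery in >= 95% of null replicates."""
    from dataclasses import replace
    cfg = replace(
        SimConfig(),
        hiv_effects={t: 0.0 for t in SimConfig().hiv_effects},
        art_effect_d=0.0, cd4_effect_d=0.0, vl_effect_d=0.0,
    )
    clean = 0
    reps = 60
    for i in range(reps):
        scored = _scored_cohort(replace(cfg, seed=500 + i))
        res = subgroup_compare(scored, "hiv")
        tests = [r for r in res if r.k == 8]
        assert all(abs(r.estimate) < 0.35 for r in tests)
        clean += all(r.adj_p >= 0.05 for r in tests)
    assert clean / reps >= 0.95


def test_empty_subgroup_is_structured_error():
    scored = _scored_cohort(SimConfig(seed=7))
    only_controls = scored[scored["group"] == "HIV-"]
    with pytest.raises(ValueError, match="empty subgroup"):
        subgroup_compare(only_controls, "hiv")


def test_subgroup_results_carry_fdr_families():
    scored = _scored_cohort(SimConfig(seed=3))
    res = subgroup_compare(scored, "hiv")
    assert sum(r.k == 8 for r in res) == 8
    assert sum(r.k == 2 for r in res) == 2
    for r in res:
        assert r.adj_p >= r.p - 1e-12
        assert r.ci_low <= r.estimate <= r.ci_high
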