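"""Fractional-polynomial norm refitting: closed test, recovery, invariants."""

import numpy as np
import pandas as pd
import pytest

from npnorm.mfp import (
    FPSpec,
    POWER_SET,
    fit_fp_covariate,
    fit_norms,
    fp_basis,
    fp_terms,
    _deviance,
    _rss,
)


def _sim_from_formula(formula, n, seed, age_hi=65, edu_hi=22):
    rng = np.random.default_rng(seed)
    age = rng.integers(18, age_hi, n)
    edu = rng.integers(0, edu_hi, n)
    male = rng.integers(0, 2, n)
    ss = formula.predicted(age, edu, male) + rng.normal(0, formula.residual_sd, n)
    return pd.DataFrame(
        {"age": age, "edu": edu, "male": male, f"{formula.test_id}_ss": ss}
    )


def test_fp_basis_repeated_powers_expand_with_log():
    x = np.array([0.5, 1.0, 2.0])
    B = fp_basis(x, (3.0, 3.0))
    assert np.allclose(B[:, 0], x**3)
    assert np.allclose(B[:, 1], x**3 * np.log(x))
    B0 = fp_basis(x, (0.0, 0.0))
    assert np.allclose(B0[:, 0], np.log(x))
    assert np.allclose(B0[:, 1], np.log(x) ** 2)
    assert fp_terms((0.0, 0.0)) == [(0.0, 1), (0.0, 2)]


def test_fp_basis_requires_positive_covariate():
    with pytest.raises(ValueError, match="positive"):
        fp_basis(np.array([-1.0, 2.0]), (1.0,))


def test_fp1_deviance_equals_brute_force_search():
    """For a 1-covariate FP1 fit, the selected deviance equals an
    exhaustive search over all 8 powers computed independently."""
    rng = np.random.default_rng(11)
    x = rng.uniform(0.2, 2.0, 300)
    y = 2 + 1.5 / x + rng.normal(0, 0.5, 300)
    sel = fit_fp_covariate(y, x, np.ones((300, 1)), FPSpec())
    brute = []
    for p in POWER_SET:
        col = np.log(x) if p == 0 else x**p
        X = np.column_stack([np.ones_like(x), col])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        brute.append((len(y) * np.log(rss / len(y)), p))
    best_dev, best_p = min(brute)
    assert sel.deviances["fp1"] == pytest.approx(best_dev, abs=1e-9)
    assert sel.deviances["fp1_powers"] == (best_p,)


def test_fp2_power_recovery_under_strong_truth():
    """FP2(3,3) truth with large effects is recovered in >= 90% of
    simulation replicates (the generating model is the oracle)."""
    hits = 0
    reps = 200
    for i in range(reps):
        rng = np.random.default_rng(10_000 + i)
        x = rng.uniform(0.1, 2.2, 350)
        y = 1 + 4 * x**3 - 3 * x**3 * np.log(x) + rng.normal(0, 1, 350)
        sel = fit_fp_covariate(y, x, np.ones((350, 1)), FPSpec())
        hits += sel.form == "fp2" and sel.powers == (3.0, 3.0)
    assert hits / reps >= 0.90


def test_closed_test_stops_at_linear_under_linear_truth():
    stops = 0
    reps = 100
    for i in range(reps):
        rng = np.random.default_rng(20_000 + i)
        x = rng.uniform(0.1, 2.2, 350)
        y = 1 + 2 * x + rng.normal(0, 1, 350)
        sel = fit_fp_covariate(y, x, np.ones((350, 1)), FPSpec(alpha=0.05))
        stops += sel.form == "linear"
    # closed test should retain linear in about 1 - alpha of replicates
    assert stops / reps >= 1 - 0.05 - 0.05


def test_forced_covariate_retained_under_independence():
    rng = np.random.default_rng(5)
    x = rng.uniform(0.2, 2.0, 400)
    y = rng.normal(0, 1, 400)
    sel = fit_fp_covariate(y, x, np.ones((400, 1)), FPSpec(forced=True))
    assert sel.form in ("linear", "fp1", "fp2")  # never dropped
    # linear coefficient CI covers 0 (Wald from an independent OLS fit)
    X = np.column_stack([np.ones_like(x), x])
    beta, rss = _rss(X, y)
    se = np.sqrt(rss / (len(y) - 2) * np.linalg.inv(X.T @ X)[1, 1])
    assert abs(beta[1]) < 1.96 * se


def test_unforced_covariate_dropped_under_independence():
    rng = np.random.default_rng(6)
    x = rng.uniform(0.2, 2.0, 400)
    y = rng.normal(0, 1, 400)
    sel = fit_fp_covariate(y, x, np.ones((400, 1)), FPSpec(forced=False))
    assert sel.form == "none"


def test_parameter_recovery_from_shipped_formula(formulas):
    """Refit on n=2000 simulated from the published model recovers the
    coefficients within 15% and residual SD within 10%."""
    f = formulas["gp_dh"]
    df = _sim_from_formula(f, 2000, seed=0)
    fit = fit_norms(df, "gp_dh")
    got = {(t.var, t.power): t.coef for t in fit.terms}
    assert set(got) == {("edu", 1.0), ("age", 1.0), ("male", 1.0)}
    assert fit.intercept == pytest.approx(f.intercept, rel=0.15)
    assert got[("edu", 1.0)] == pytest.approx(2.1445, rel=0.15)
    assert got[("age", 1.0)] == pytest.approx(-8.0012, rel=0.15)
    assert fit.residual_sd == pytest.approx(f.residual_sd, rel=0.10)


def test_null_demographic_effects_recovered(formulas):
    """With no true demographic effects the coefficient CIs cover 0 and
    corrected T scores carry no residual demographic slope."""
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    n = 1500
    age = rng.integers(18, 65, n)
    edu = rng.integers(0, 22, n)
    male = rng.integers(0, 2, n)
    ss = 10 + rng.normal(0, 2.6, n)
    df = pd.DataFrame({"age": age, "edu": edu, "male": male, "gp_dh_ss": ss})
    fit = fit_norms(df, "gp_dh")
    t = 50 + 10 * (ss - fit.predicted(age, edu, male)) / fit.residual_sd
    for cov in (age, edu, male):
        X = sm.add_constant(np.asarray(cov, dtype=float))
        res = sm.OLS(t, X).fit()
        lo, hi = res.conf_int()[1]
        assert lo <= 0 <= hi
        assert abs(res.params[1]) < 0.02  # T units per unit covariate


def test_refit_is_deterministic(formulas):
    df = _sim_from_formula(formulas["tmt_a"], 800, seed=3)
    assert fit_norms(df, "tmt_a") == fit_norms(df, "tmt_a")


def test_self_norming_property(formulas):
    """T from a formula fitted on X has mean exactly 50 on X and SD near
    10 (slightly below because residual_sd uses n - p)."""
    f = formulas["stroop_color"]
    df = _sim_from_formula(f, 1200, seed=8)
    fit = fit_norms(df, "stroop_color")
    y = df["stroop_color_ss"].to_numpy()
    t = 50 + 10 * (y - fit.predicted(df["age"], df["edu"], df["male"])) / fit.residual_sd
    assert t.mean() == pytest.approx(50.0, abs=1e-8)
    assert t.std(ddof=1) == pytest.approx(10.0, abs=0.2)
    assert t.std(ddof=1) < 10.0  # documented n - p offset


_COMPLEXITY = {"none": 0, "linear": 1, "fp1": 2, "fp2": 3}


def test_lower_alpha_never_selects_more_complex_form():
    for i in range(25):
        rng = np.random.default_rng(30_000 + i)
        x = rng.uniform(0.1, 2.2, 300)
        y = 1 + rng.uniform(-2, 2) * x + rng.uniform(-1, 1) * x**2 \
            + rng.normal(0, 1, 300)
        forms = [
            fit_fp_covariate(y, x, np.ones((300, 1)), FPSpec(alpha=a)).form
            for a in (0.01, 0.05, 0.2)
        ]
        assert _COMPLEXITY[forms[0]] <= _COMPLEXITY[forms[1]] <= _COMPLEXITY[forms[2]]


def test_small_sample_rejected(formulas):
    df = _sim_from_formula(formulas["gp_dh"], 50, seed=1)
    with pytest.raises(ValueError, match="too small"):
        fit_norms(df, "gp_dh")
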