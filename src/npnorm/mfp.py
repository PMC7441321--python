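"""Multivariable fractional polynomial (MFP) norm fitting.

Refits the norming model from any normative sample: scaled scores are
regressed on education, age and sex, with the functional form of the two
continuous covariates chosen from the fractional-polynomial family over
the conventional power set S = {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 = log).
An FP1 model uses one power x^p; an FP2 model uses x^p1 + x^p2, with a
repeated power (p, p) expanding to x^p and x^p * log x.

Model selection per covariate follows the Royston-Altman closed test on
deviance differences (Gaussian deviance n * log(RSS/n)) with conventional
FP degrees of freedom:

1. best FP2 vs the model omitting the covariate (df 4) - skipped for
   forced covariates, which are retained at least linearly;
2. best FP2 vs linear (df 3): stop at linear if not significant;
3. best FP2 vs best FP1 (df 2): FP1 if not significant, else FP2.

All three demographics are forced by default and sex always enters
linearly; selection cycles over education and age until the chosen forms
stabilise. The fit is deterministic ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .tscore import FPTerm, TScoreFormula

POWER_SET = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPSpec:
    """Configuration of the FP search and closed-test selection."""

    powers: tuple[float, ...] = POWER_SET
    max_degree: int = 2
    alpha: float = 0.05
    forced: bool = True  # retain the covariate (at least linearly) regardless
    max_cycles: int = 5

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not self.powers:
            raise ValueError("power set must be non-empty")


def fp_basis(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Design columns for an FP with the given (sorted) power tuple.

    Power 0 is log x; a repeated power p contributes x^p and x^p log x
    (hence (0, 0) gives log x and (log x)^2).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("FP covariate must be strictly positive")
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        rep = seen.get(p, 0)
        base = np.log(x) if p == 0 else x**p
        cols.append(base * np.log(x) ** rep if rep else base)
        seen[p] = rep + 1
    return np.column_stack(cols)


def fp_terms(powers: tuple[float, ...]) -> list[tuple[float, int]]:
    """(power, log_mult) pairs matching the columns of :func:`fp_basis`."""
    out, seen = [], {}
    for p in powers:
        rep = seen.get(p, 0)
        if p == 0:
            out.append((0.0, rep + 1))  # log x, (log x)^2, ...
        else:
            out.append((p, rep))
        seen[p] = rep + 1
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


def _deviance(rss: float, n: int) -> float:
    return n * np.log(rss / n)


@dataclass
class FPSelection:
    """Outcome of the closed-test selection for one covariate."""

    form: str  # "none", "linear", "fp1" or "fp2"
    powers: tuple[float, ...]  # () for none, (1,) for linear
    coefs: np.ndarray  # coefficients of [others | selected transform]
    deviances: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)


def fit_fp_covariate(
    y, x, others: np.ndarray | None, spec: FPSpec = FPSpec()
) -> FPSelection:
    """Select the FP form for one covariate, adjusting for ``others``.

    ``others`` is the design matrix of the remaining linear predictor
    (including the intercept column); ``x`` is the pre-transformed,
    strictly positive covariate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    Z = np.ones((n, 1)) if others is None else np.asarray(others, dtype=float)
    n_candidate = Z.shape[1] + 2 * spec.max_degree
    if n <= 10 * n_candidate:
        raise ValueError(f"sample too small for FP selection: n={n}")

    def dev(powers):
        X = Z if powers is None else np.hstack([Z, fp_basis(x, powers)])
        beta, rss = _rss(X, y)
        return _deviance(rss, n), beta

    d_null, b_null = dev(None)
    d_lin, b_lin = dev((1.0,))
    best1 = min(
        ((dev((p,)), (p,)) for p in spec.powers), key=lambda t: t[0][0]
    )
    (d_fp1, b_fp1), pow1 = best1
    best2 = min(
        ((dev(pp), pp) for pp in combinations_with_replacement(sorted(spec.powers), 2)),
        key=lambda t: t[0][0],
    )
    (d_fp2, b_fp2), pow2 = best2

    devs = {"null": d_null, "linear": d_lin, "fp1": d_fp1, "fp2": d_fp2,
            "fp1_powers": pow1, "fp2_powers": pow2}
    pv = {}
    if not spec.forced:
        pv["fp2_vs_null"] = chi2.sf(max(d_null - d_fp2, 0.0), 4)
        if pv["fp2_vs_null"] >= spec.alpha:
            return FPSelection("none", (), b_null, devs, pv)
    pv["fp2_vs_linear"] = chi2.sf(max(d_lin - d_fp2, 0.0), 3)
    if pv["fp2_vs_linear"] >= spec.alpha:
        return FPSelection("linear", (1.0,), b_lin, devs, pv)
    pv["fp2_vs_fp1"] = chi2.sf(max(d_fp1 - d_fp2, 0.0), 2)
    if pv["fp2_vs_fp1"] >= spec.alpha:
        return FPSelection("fp1", pow1, b_fp1, devs, pv)
    return FPSelection("fp2", pow2, b_fp2, devs, pv)


def _design(edu_t, age_t, male, forms: dict[str, tuple[float, ...]]):
    """Full design [1 | edu FP | age FP | male] for the given forms."""
    n = len(male)
    cols = [np.ones(n)]
    layout = []
    for var, x in (("edu", edu_t), ("age", age_t)):
        pws = forms[var]
        if pws:
            B = fp_basis(x, pws)
            cols.append(B)
            layout += [(var, p, lm) for p, lm in fp_terms(pws)]
    cols.append(np.asarray(male, dtype=float).reshape(-1, 1))
    layout.append(("male", 1.0, 0))
    return np.hstack([c if c.ndim == 2 else c.reshape(-1, 1) for c in cols]), layout


def fit_norms(
    sample: pd.DataFrame,
    test_id: str,
    spec: FPSpec = FPSpec(),
    scaled_col: str | None = None,
    full_output: bool = False,
):
    """Fit the norming model for one test on a normative sample.

    ``sample`` needs columns ``age``, ``edu``, ``male`` and the scaled
    scores (``<test_id>_ss`` by default). Cycles FP selection over
    education and age (sex always linear), then refits the selected model
    by least squares; ``residual_sd`` is the root mean squared residual
    with an n - p degrees-of-freedom correction. Returns a
    :class:`~npnorm.tscore.TScoreFormula` (and a fit report when
    ``full_output``).
    """
    col = scaled_col or f"{test_id}_ss"
    need = ["age", "edu", "male", col]
    missing = [c for c in need if c not in sample.columns]
    if missing:
        raise ValueError(f"sample missing columns: {missing}")
    df = sample[need].dropna()
    y = df[col].to_numpy(dtype=float)
    edu_t = (df["edu"].to_numpy(dtype=float) + 1.0) / 10.0
    age_t = df["age"].to_numpy(dtype=float) / 100.0
    male = df["male"].to_numpy(dtype=float)
    n = len(y)
    if n <= 10 * (2 + 2 * spec.max_degree):
        raise ValueError(f"normative sample too small: n={n}")

    forms = {"edu": (1.0,), "age": (1.0,)}
    selections: dict[str, FPSelection] = {}
    history = []
    for _ in range(spec.max_cycles):
        prev = dict(forms)
        for var, x in (("edu", edu_t), ("age", age_t)):
            other = "age" if var == "edu" else "edu"
            cols = [np.ones(n)]
            if forms[other]:
                ox = age_t if other == "age" else edu_t
                cols.append(fp_basis(ox, forms[other]))
            cols.append(male.reshape(-1, 1))
            Z = np.hstack([c if c.ndim == 2 else c.reshape(-1, 1) for c in cols])
            sel = fit_fp_covariate(y, edu_t if var == "edu" else age_t, Z, spec)
            forms[var] = sel.powers
            selections[var] = sel
        history.append(dict(forms))
        if forms == prev:
            break

    X, layout = _design(edu_t, age_t, male, forms)
    beta, rss = _rss(X, y)
    p = X.shape[1]
    residual_sd = float(np.sqrt(rss / (n - p)))
    terms = tuple(
        FPTerm(var, power, log_mult, float(c))
        for (var, power, log_mult), c in zip(layout, beta[1:])
    )
    formula = TScoreFormula(
        test_id=test_id,
        intercept=float(beta[0]),
        terms=terms,
        residual_sd=residual_sd,
    )
    if not full_output:
        return formula
    report = {
        "n": n,
        "forms": forms,
        "cycles": history,
        "selections": {
            v: {"form": s.form, "powers": s.powers, "deviances": s.deviances,
                "pvalues": s.pvalues}
            for v, s in selections.items()
        },
        "coefficients": {"intercept": float(beta[0]),
                         **{f"{t.var}^{t.power}" + ("*log^%d" % t.log_mult if t.log_mult else ""): t.coef
                            for t in terms}},
        "residual_sd": residual_sd,
        "rss": rss,
    }
    return formula, report
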