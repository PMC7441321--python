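"""Group-comparison statistics: effect sizes, odds ratios, FDR, regressions.

Implements the statistical layer of the norming study: case-control
T-score comparisons (Cohen's d with pooled SD, two-sample t on the pooled
variance), impairment-proportion comparisons (odds ratios with Wald CIs on
the log scale), demographic-effect regressions (univariable and
multivariable OLS), subgroup contrasts, Fisher's exact test, and
Benjamini-Hochberg FDR adjustment with the study's family sizes (k = 8
individual tests, k = 2 domain summaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .registry import TESTS

Z975 = 1.959963984540054


@dataclass
class ComparisonResult:
    """One estimated contrast with CI and raw/FDR-adjusted p-values."""

    label: str
    kind: str  # "cohens_d" | "odds_ratio" | "coefficient" | "mean_diff"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    adj_p: float | None = None
    k: int | None = None  # FDR family size
    n1: int | None = None
    n2: int | None = None
    extra: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        """Report-parity rounding: estimates/CIs to 2 dp, p to 3 dp."""
        r = lambda v, nd: None if v is None or not np.isfinite(v) else round(v, nd)
        return {
            "label": self.label,
            "kind": self.kind,
            "estimate": r(self.estimate, 2),
            "ci": (r(self.ci_low, 2), r(self.ci_high, 2)),
            "p": r(self.p, 3),
            "adj_p": r(self.adj_p, 3) if self.adj_p is not None else None,
            "n1": self.n1,
            "n2": self.n2,
        }


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    label: str = "", noncentral_ci: bool = False,
) -> ComparisonResult:
    """Cohen's d for group 2 vs group 1 with pooled SD.

    d = (mean2 - mean1)/s_pooled, s_pooled^2 = ((n1-1)sd1^2 +
    (n2-1)sd2^2)/(n1+n2-2). The default CI uses the normal-approximation
    SE(d) = sqrt(1/n1 + 1/n2 + d^2/(2(n1+n2))); ``noncentral_ci`` switches
    to the exact noncentral-t interval.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("degenerate variance")
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean2 - mean1) / sp
    se = math.sqrt(1 / n1 + 1 / n2 + d**2 / (2 * (n1 + n2)))
    if noncentral_ci:
        nc = d / math.sqrt(1 / n1 + 1 / n2)
        df = n1 + n2 - 2
        lo_nc, hi_nc = _noncentral_t_ci(nc, df)
        lo, hi = (lo_nc * math.sqrt(1 / n1 + 1 / n2), hi_nc * math.sqrt(1 / n1 + 1 / n2))
    else:
        lo, hi = d - Z975 * se, d + Z975 * se
    # two-sample pooled t-test p from the summary statistics
    tstat = (mean2 - mean1) / (sp * math.sqrt(1 / n1 + 1 / n2))
    p = 2 * st.t.sf(abs(tstat), n1 + n2 - 2)
    return ComparisonResult(label, "cohens_d", d, lo, hi, p, n1=n1, n2=n2,
                            extra={"t": tstat, "pooled_sd": sp})


def _noncentral_t_ci(nc_obs: float, df: float) -> tuple[float, float]:
    from scipy.optimize import brentq

    def lo_f(nc):
        return st.nct.sf(nc_obs, df, nc) - 0.025

    def hi_f(nc):
        return st.nct.cdf(nc_obs, df, nc) - 0.025

    span = abs(nc_obs) + 10
    return brentq(lo_f, -span - 10, span + 10), brentq(hi_f, -span - 10, span + 10)


def odds_ratio(
    impaired1: int, total1: int, impaired2: int, total2: int,
    label: str = "", continuity: bool = False,
) -> ComparisonResult:
    """Odds ratio of impairment in group 2 relative to group 1.

    OR = (impaired2/unimpaired2) / (impaired1/unimpaired1) with a Wald 95%
    CI exp(log OR +- 1.96 sqrt(sum 1/cell)). Zero cells raise unless
    ``continuity`` adds 0.5 to every cell. The p-value is the Wald z test
    on log OR (asymptotically the logistic-regression group test).
    """
    a, b = impaired2, total2 - impaired2
    c, d = impaired1, total1 - impaired1
    if min(a, b, c, d) < 0:
        raise ValueError("impaired counts exceed totals or are negative")
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError("zero cell in 2x2 table; enable continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - Z975 * se)
    hi = math.exp(math.log(orr) + Z975 * se)
    z = math.log(orr) / se
    p = 2 * st.norm.sf(abs(z))
    return ComparisonResult(label, "odds_ratio", orr, lo, hi, p,
                            n1=total1, n2=total2,
                            extra={"cells": (a, b, c, d)})


def bh_adjust(pvalues, k: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} (p_(j) * k / j), capped at 1, returned in the
    input order. ``k`` must equal the family size (len(pvalues)); it is
    accepted explicitly because the study reports family sizes (8 tests,
    2 summaries) alongside the adjusted values.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    if k is not None and k != len(p):
        raise ValueError(f"family size k={k} != number of p-values {len(p)}")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test (point-probability rule) on a 2x2
    table [[a, b], [c, d]]; returns (odds ratio, p)."""
    orr, p = st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def _ols_results(y, X, names, label_prefix, kind="coefficient"):
    model = sm.OLS(y, X).fit()
    ci = model.conf_int()
    out = []
    for i, name in enumerate(names):
        out.append(
            ComparisonResult(
                f"{label_prefix}{name}", kind,
                float(model.params[i]), float(ci[i][0]), float(ci[i][1]),
                float(model.pvalues[i]),
                extra={"se": float(model.bse[i]), "cond": float(np.linalg.cond(X))},
            )
        )
    return out, model


def demographic_regression(
    tscores, age, edu, male, multivariable: bool = True
) -> list[ComparisonResult]:
    """Regress T scores on demographics (complete cases).

    Returns per-covariate coefficients with Wald 95% CIs: the three
    univariable fits plus (by default) the multivariable fit. Labels are
    prefixed ``uni:`` / ``multi:``. A well-normed sample should show
    coefficients near 0.
    """
    df = pd.DataFrame(
        {"t": tscores, "age": age, "edu": edu, "male": male}
    ).dropna()
    n = len(df)
    if n <= 10 * 4:
        raise ValueError(f"too few complete cases: n={n}")
    y = df["t"].to_numpy(dtype=float)
    results = []
    for var in ("age", "edu", "male"):
        X = sm.add_constant(df[var].to_numpy(dtype=float))
        res, _ = _ols_results(y, X, ["const", var], "uni:")
        results.append(res[1])
    if multivariable:
        X = sm.add_constant(df[["age", "edu", "male"]].to_numpy(dtype=float))
        res, _ = _ols_results(y, X, ["const", "age", "edu", "male"], "multi:")
        results.extend(res[1:])
    return results


def _two_group_d(df: pd.DataFrame, col: str, mask1, mask2, label: str):
    x1 = df.loc[mask1, col].dropna()
    x2 = df.loc[mask2, col].dropna()
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError(f"{label}: subgroup too small (n={len(x1)}, {len(x2)})")
    return cohens_d(
        float(x1.mean()), float(x1.std(ddof=1)), len(x1),
        float(x2.mean()), float(x2.std(ddof=1)), len(x2),
        label=label,
    )


GROUPINGS = {
    # grouping name -> (reference mask fn, comparison mask fn, description)
    "hiv": (lambda d: d["group"] == "HIV-", lambda d: d["group"] == "HIV+"),
    "art": (
        lambda d: (d["group"] == "HIV+") & (d["art_status"] != "on-ART"),
        lambda d: (d["group"] == "HIV+") & (d["art_status"] == "on-ART"),
    ),
    "cd4": (
        lambda d: (d["group"] == "HIV+") & (d["cd4"] < 350),
        lambda d: (d["group"] == "HIV+") & (d["cd4"] >= 350),
    ),
    "vl": (
        lambda d: (d["group"] == "HIV+") & (~d["vl_detectable"].astype("boolean").fillna(False)),
        lambda d: (d["group"] == "HIV+") & (d["vl_detectable"].astype("boolean").fillna(False)),
    ),
}


def subgroup_compare(
    scored: pd.DataFrame, grouping: str = "hiv"
) -> list[ComparisonResult]:
    """Per-test and per-summary Cohen's d for a two-group contrast.

    ``grouping`` is one of ``hiv``, ``art``, ``cd4``, ``vl`` or
    ``treatment_success`` (three groups: untreated, on-ART detectable VL,
    on-ART undetectable VL; emits the pairwise contrasts). FDR families
    follow the study layout: the 8 individual tests are one family (k=8),
    the 2 domain summaries another (k=2).
    """
    if grouping == "treatment_success":
        return _treatment_success(scored)
    if grouping not in GROUPINGS:
        raise KeyError(f"unknown grouping {grouping!r}")
    m1f, m2f = GROUPINGS[grouping]
    m1, m2 = m1f(scored), m2f(scored)
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"grouping {grouping!r}: empty subgroup")
    tests = [
        _two_group_d(scored, f"{tid}_t", m1, m2, f"{grouping}:{tid}") for tid in TESTS
    ]
    summaries = [
        _two_group_d(scored, f"{dom}_t", m1, m2, f"{grouping}:{dom}_summary")
        for dom in ("motor", "sip")
    ]
    apply_fdr_families(tests, summaries)
    return tests + summaries


def apply_fdr_families(tests: list[ComparisonResult], summaries: list[ComparisonResult]):
    """BH-adjust in place with the study's family sizes."""
    for fam in (tests, summaries):
        if not fam:
            continue
        adj = bh_adjust([r.p for r in fam], k=len(fam))
        for r, a in zip(fam, adj):
            r.adj_p, r.k = a, len(fam)


def _treatment_success(scored: pd.DataFrame) -> list[ComparisonResult]:
    cases = scored[scored["group"] == "HIV+"]
    det = cases["vl_detectable"].astype("boolean")
    groups = {
        "untreated": cases["art_status"] != "on-ART",
        "art_detectable": (cases["art_status"] == "on-ART") & det.fillna(False),
        "art_undetectable": (cases["art_status"] == "on-ART") & ~det.fillna(True),
    }
    pairs = [
        ("untreated", "art_detectable"),
        ("untreated", "art_undetectable"),
        ("art_detectable", "art_undetectable"),
    ]
    out = []
    for g1, g2 in pairs:
        tests = [
            _two_group_d(cases, f"{tid}_t", groups[g1], groups[g2],
                         f"{g2}_vs_{g1}:{tid}")
            for tid in TESTS
        ]
        summaries = [
            _two_group_d(cases, f"{dom}_t", groups[g1], groups[g2],
                         f"{g2}_vs_{g1}:{dom}_summary")
            for dom in ("motor", "sip")
        ]
        apply_fdr_families(tests, summaries)
        out.extend(tests + summaries)
    return out


def impairment_compare(classified: pd.DataFrame) -> list[ComparisonResult]:
    """Case-control odds ratios of impairment per test and per domain."""
    ctrl = classified["group"] == "HIV-"
    case = classified["group"] == "HIV+"

    def counts(col, mask):
        v = classified.loc[mask, col]
        v = v.dropna()
        return int(v.sum()), len(v)

    tests, summaries = [], []
    for tid in TESTS:
        i1, t1 = counts(f"{tid}_impaired", ctrl)
        i2, t2 = counts(f"{tid}_impaired", case)
        tests.append(odds_ratio(i1, t1, i2, t2, label=f"impair:{tid}", continuity=True))
    for dom in ("motor", "sip"):
        i1, t1 = counts(f"{dom}_impaired", ctrl)
        i2, t2 = counts(f"{dom}_impaired", case)
        summaries.append(
            odds_ratio(i1, t1, i2, t2, label=f"impair:{dom}_summary", continuity=True)
        )
    apply_fdr_families(tests, summaries)
    return tests + summaries
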