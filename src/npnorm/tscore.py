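"""Demographically corrected T scores from fractional-polynomial formulas.

Each test has a published formula predicting the scaled score expected of
a healthy adult given education, age and sex; the T score standardises the
residual onto a mean-50, SD-10 scale:

    T = 50 + 10 * (scaled - predicted(edu, age, male)) / residual_sd

Covariates enter pre-transformed: ``edu_t = (edu + 1)/10`` and
``age_t = age/100`` (so a log or negative power is defined for edu = 0),
``male`` coded 1 for men, 0 for women. Predicted scores are fractional
polynomials in these transforms; the shipped set
(``data/cameroon_2020_tscores.json``) uses linear terms, ``x^3``,
``x^-2`` and ``log(x) * x^3``, but any power with an optional log
multiplier is supported so refitted formulas round-trip.

Domain summary T scores are unweighted means of the component tests
(motor: 2 tests; SIP: 6), reported only when all components are present.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import DOMAINS, MOTOR_TESTS, SIP_TESTS, TESTS, check_test_id

AGE_RANGE = (18, 64)
EDU_MAX = 21


@dataclass(frozen=True)
class FPTerm:
    """One fractional-polynomial term: var^power * log(var)^log_mult.

    ``log_mult`` is 0 for a plain power, 1 for the log-multiplied twin of
    a repeated power (and 2 for the (log x)^2 twin of a repeated log).
    """

    var: str  # "edu", "age" or "male" (edu/age refer to the pre-transforms)
    power: float
    log_mult: int
    coef: float

    def value(self, edu_t, age_t, male):
        if self.var == "male":
            return self.coef * male
        x = edu_t if self.var == "edu" else age_t
        v = np.power(x, self.power)
        if self.log_mult:
            v = v * np.log(x) ** self.log_mult
        return self.coef * v


@dataclass(frozen=True)
class TScoreFormula:
    test_id: str
    intercept: float
    terms: tuple[FPTerm, ...]
    residual_sd: float

    def __post_init__(self):
        if not (self.residual_sd > 0 and np.isfinite(self.residual_sd)):
            raise ValueError(f"{self.test_id}: residual_sd must be positive")
        if not all(np.isfinite(t.coef) for t in self.terms):
            raise ValueError(f"{self.test_id}: non-finite coefficient")

    def predicted(self, age, edu, male):
        """Predicted scaled score for the given demographics (vectorised)."""
        edu_t = (np.asarray(edu, dtype=float) + 1.0) / 10.0
        age_t = np.asarray(age, dtype=float) / 100.0
        male = np.asarray(male, dtype=float)
        out = self.intercept + sum(t.value(edu_t, age_t, male) for t in self.terms)
        return out

    def to_dict(self) -> dict:
        return {
            "test_id": self.test_id,
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "terms": [
                {"var": t.var, "power": t.power, "log_mult": t.log_mult, "coef": t.coef}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TScoreFormula":
        return cls(
            test_id=d["test_id"],
            intercept=float(d["intercept"]),
            residual_sd=float(d["residual_sd"]),
            terms=tuple(
                FPTerm(t["var"], float(t["power"]), int(t["log_mult"]), float(t["coef"]))
                for t in d["terms"]
            ),
        )


def load_tscore_formulas(path=None) -> dict[str, TScoreFormula]:
    """Load a formula set from JSON; defaults to the packaged Cameroonian set."""
    if path is None:
        text = (
            resources.files("npnorm") / "data" / "cameroon_2020_tscores.json"
        ).read_text()
    else:
        with open(path, encoding="utf-8") as f:
            text = f.read()
    doc = json.loads(text)
    return {f["test_id"]: TScoreFormula.from_dict(f) for f in doc["formulas"]}


def save_tscore_formulas(formulas: dict[str, TScoreFormula], path, name="tscore_formulas"):
    doc = {"name": name, "formulas": [f.to_dict() for f in formulas.values()]}
    with open(path, "w", encoding="utf-8") as f:
        json.dump(doc, f, indent=1)


def compute_t(
    formula: TScoreFormula,
    scaled,
    age,
    edu,
    male,
    warnings: list | None = None,
) -> float:
    """T score for one subject-test. Demographics outside the normed range
    (age 18-64, education 0-21) warn but the formula is still evaluated as
    published. T scores are not truncated or rounded."""
    if warnings is not None:
        if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
            warnings.append(
                {"test_id": formula.test_id, "issue": f"age {age} outside normed range 18-64"}
            )
        if edu > EDU_MAX:
            warnings.append(
                {"test_id": formula.test_id, "issue": f"education {edu} above normed maximum 21"}
            )
    if edu < 0:
        raise ValueError("education must be >= 0")
    return float(
        50.0 + 10.0 * (scaled - formula.predicted(age, edu, male)) / formula.residual_sd
    )


def summary_t(
    domain: str, t_scores: Mapping[str, float], warnings: list | None = None
) -> float:
    """Domain summary T: unweighted mean of component T scores.

    Returns NaN (with a warning record) unless every component test of the
    domain has a finite T score.
    """
    comps = DOMAINS[domain]
    vals = [t_scores.get(t, np.nan) for t in comps]
    if any(v is None or not np.isfinite(v) for v in vals):
        if warnings is not None:
            missing = [t for t, v in zip(comps, vals) if v is None or not np.isfinite(v)]
            warnings.append(
                {"domain": domain, "issue": f"missing component T scores: {missing}"}
            )
        return float("nan")
    return float(np.mean(vals))


def score_dataframe(
    df: pd.DataFrame,
    tables: Mapping[str, "npnorm.norm_tables.NormLookupTable"] | None = None,
    formulas: Mapping[str, TScoreFormula] | None = None,
) -> pd.DataFrame:
    """Score a subject table end to end: raw -> scaled -> T -> summaries.

    Expects columns ``age``, ``edu``, ``male`` and ``<test>_raw`` per test;
    returns a copy with ``<test>_ss``, ``<test>_t``, ``motor_t`` and
    ``sip_t`` appended. Missing raw scores propagate as NaN; a summary T is
    NaN whenever any component is missing.
    """
    from .norm_tables import load_norm_tables, raw_to_scaled_array

    tables = tables if tables is not None else load_norm_tables()
    formulas = formulas if formulas is not None else load_tscore_formulas()
    out = df.copy()
    for tid in TESTS:
        col = f"{tid}_raw"
        if col not in out.columns:
            continue
        ss = raw_to_scaled_array(tables[tid], out[col].to_numpy(dtype=float))
        out[f"{tid}_ss"] = ss
        f = formulas[tid]
        pred = f.predicted(out["age"], out["edu"], out["male"])
        out[f"{tid}_t"] = 50.0 + 10.0 * (ss - pred) / f.residual_sd
    motor = [f"{t}_t" for t in MOTOR_TESTS]
    sip = [f"{t}_t" for t in SIP_TESTS]
    out["motor_t"] = out[motor].mean(axis=1).where(out[motor].notna().all(axis=1))
    out["sip_t"] = out[sip].mean(axis=1).where(out[sip].notna().all(axis=1))
    return out
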