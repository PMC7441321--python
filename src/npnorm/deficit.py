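"""Deficit scores and impairment classification.

A T score is recoded onto the standard 0-5 deficit scale emphasising
impairment severity (0 = no deficit, performance at or above one SD below
the demographic expectation; 5 = severe deficit). A test is impaired when
its deficit score is >= 1 (T < 40); a domain is impaired when the mean of
its component deficit scores exceeds 0.5 (strictly), so e.g. deficits
{0, 1} over two tests give a mean of exactly 0.5 and are NOT impaired.

The T -> deficit breakpoints live in one data table (DEFICIT_BREAKPOINTS)
so alternative conventions can be swapped in.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .registry import DOMAINS, MOTOR_TESTS, SIP_TESTS, TESTS

# (T lower bound inclusive, deficit score); scanned top down
DEFICIT_BREAKPOINTS: tuple[tuple[float, int], ...] = (
    (40.0, 0),
    (35.0, 1),
    (30.0, 2),
    (25.0, 3),
    (20.0, 4),
    (-math.inf, 5),
)

DOMAIN_IMPAIRMENT_CUTOFF = 0.5  # strict: mean deficit must exceed this


def t_to_deficit(t: float) -> int:
    """Deficit score (0-5) for a T score; NaN propagates as NaN."""
    if t is None or (isinstance(t, float) and math.isnan(t)):
        return float("nan")
    if not math.isfinite(t):
        raise ValueError(f"non-finite T score {t}")
    for lower, score in DEFICIT_BREAKPOINTS:
        if t >= lower:
            return score
    raise AssertionError("unreachable")


def t_to_deficit_array(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, np.nan)
    for lower, score in reversed(DEFICIT_BREAKPOINTS):
        out[t >= lower] = score
    out[~np.isfinite(t)] = np.nan
    return out


def classify(
    deficits: Mapping[str, float], warnings: list | None = None
) -> dict:
    """Aggregate per-test deficit scores into a deficit profile.

    Returns per-test impairment flags (deficit >= 1), per-domain mean
    deficit scores and domain impairment flags (mean > 0.5, strict).
    Domains with any missing component get NaN/None with a warning.
    """
    profile: dict = {"test_deficit": {}, "test_impaired": {}}
    for tid, d in deficits.items():
        profile["test_deficit"][tid] = d
        profile["test_impaired"][tid] = (
            None if d is None or (isinstance(d, float) and math.isnan(d)) else d >= 1
        )
    for domain, comps in DOMAINS.items():
        vals = [deficits.get(t) for t in comps]
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
            if warnings is not None:
                missing = [
                    t for t, v in zip(comps, vals)
                    if v is None or (isinstance(v, float) and math.isnan(v))
                ]
                warnings.append(
                    {"domain": domain, "issue": f"missing component deficits: {missing}"}
                )
            profile[f"{domain}_dds"] = float("nan")
            profile[f"{domain}_impaired"] = None
        else:
            dds = float(np.mean(vals))
            profile[f"{domain}_dds"] = dds
            profile[f"{domain}_impaired"] = dds > DOMAIN_IMPAIRMENT_CUTOFF
    return profile


def classify_dataframe(scored: pd.DataFrame) -> pd.DataFrame:
    """Append deficit/impairment columns to a scored subject table.

    Adds ``<test>_deficit``, ``<test>_impaired``, ``motor_dds``,
    ``sip_dds``, ``motor_impaired`` and ``sip_impaired``. Domain values
    are missing whenever any component T score is missing.
    """
    out = scored.copy()
    for tid in TESTS:
        tcol = f"{tid}_t"
        if tcol not in out.columns:
            continue
        d = t_to_deficit_array(out[tcol].to_numpy(dtype=float))
        out[f"{tid}_deficit"] = d
        out[f"{tid}_impaired"] = pd.array(d >= 1, dtype="boolean")
        out.loc[~np.isfinite(d), f"{tid}_impaired"] = pd.NA
    for domain, comps in DOMAINS.items():
        cols = [f"{t}_deficit" for t in comps]
        if not all(c in out.columns for c in cols):
            continue
        complete = out[cols].notna().all(axis=1)
        dds = out[cols].mean(axis=1).where(complete)
        out[f"{domain}_dds"] = dds
        imp = pd.array(dds > DOMAIN_IMPAIRMENT_CUTOFF, dtype="boolean")
        imp[~complete.to_numpy()] = pd.NA
        out[f"{domain}_impaired"] = imp
    return out
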