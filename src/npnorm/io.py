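"""Subject CSV reading and validation.

The interchange format is a UTF-8 CSV with one row per participant:
``id, group, age, edu, sex`` plus ``<test>_raw`` columns (any subset of
the eight tests) and optional HIV covariates ``cd4, vl_detectable,
log10_vl, art_status``. Validation produces row-level warning records,
never silent drops; only structural problems (missing mandatory columns,
unparseable file) raise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import TESTS
from .tscore import AGE_RANGE, EDU_MAX

MANDATORY = ("id", "group", "age", "edu", "sex")
SEX_CODES = {"male", "female", "m", "f"}
GROUP_CODES = {"HIV+", "HIV-"}


class SchemaError(ValueError):
    """Input file does not match the documented subject schema."""


def read_subjects(path, schema=None) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate a subject CSV.

    Returns ``(dataframe, warnings)``. The frame gains a numeric ``male``
    column (1/0 from ``sex``). Out-of-range ages/educations, unknown sex
    codes and negative raw scores are reported as warnings with row ids;
    the rows are kept.
    """
    mandatory = tuple(schema) if schema is not None else MANDATORY
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"unparseable subject file {path}: {e}") from e
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    raw_cols = [f"{t}_raw" for t in TESTS if f"{t}_raw" in df.columns]
    if not raw_cols:
        raise SchemaError("no <test>_raw score columns present")

    warnings: list[dict] = []

    def warn(row, issue):
        warnings.append({"row": int(row), "id": df.at[row, "id"], "issue": issue})

    sex = df["sex"].astype(str).str.strip().str.lower()
    for i in df.index[~sex.isin(SEX_CODES)]:
        warn(i, f"unknown sex code {df.at[i, 'sex']!r}")
    df["male"] = sex.isin({"male", "m"}).astype(int)

    grp = df["group"].astype(str).str.strip()
    for i in df.index[~grp.isin(GROUP_CODES)]:
        warn(i, f"unknown group code {df.at[i, 'group']!r}")
    df["group"] = grp

    age = pd.to_numeric(df["age"], errors="coerce")
    for i in df.index[(age < AGE_RANGE[0]) | (age > AGE_RANGE[1])]:
        warn(i, f"age {df.at[i, 'age']} outside normed range {AGE_RANGE}")
    edu = pd.to_numeric(df["edu"], errors="coerce")
    for i in df.index[(edu < 0) | (edu > EDU_MAX)]:
        warn(i, f"education {df.at[i, 'edu']} outside 0-{EDU_MAX}")
    for c in (("age", age), ("edu", edu)):
        for i in df.index[c[1].isna() & df[c[0]].notna()]:
            warn(i, f"non-numeric {c[0]} {df.at[i, c[0]]!r}")
    df["age"], df["edu"] = age, edu

    for col in raw_cols:
        v = pd.to_numeric(df[col], errors="coerce")
        # symbol search raw = correct minus incorrect and may be negative
        if col != "wais_ss_raw":
            for i in df.index[v < 0]:
                warn(i, f"negative raw score in {col}")
        df[col] = v
    return df, warnings
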