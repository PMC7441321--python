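"""Raw-score to scaled-score conversion tables.

A :class:`NormLookupTable` maps raw test scores (seconds for timed tests,
correct-item counts otherwise) onto integer scaled scores 1-19 normed to
mean 10, SD 3 in the normative sample. The published Cameroonian adult
tables ship with the package (``data/cameroon_2020_scaled.json``);
:func:`build_scaled_table` reconstructs such a table from any normative
sample by rank normalisation.

Lookup semantics: bins are inclusive integer ranges as printed; a raw
value falling in the sub-unit gap between two adjacent printed bins (only
possible for non-integer input) takes the lower bin. Raw values beyond the
extreme bins clamp to the nearest extreme scaled score and emit a warning
record rather than an error, since clinical data contain extremes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .registry import check_test_id

HIGHER = "higher-raw-is-better"
LOWER = "lower-raw-is-better"


@dataclass(frozen=True)
class NormLookupTable:
    """Per-test raw-to-scaled conversion table.

    ``bins`` is kept sorted ascending by raw score; for time tests the
    scaled scores therefore run 19..1 down the list.
    """

    test_id: str
    direction: str  # HIGHER or LOWER
    units: str  # "seconds" or "count"
    bins: tuple[tuple[float, float, int], ...]  # (raw_lo, raw_hi, scaled)

    def __post_init__(self):
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"bad direction {self.direction!r}")
        b = sorted(self.bins, key=lambda x: x[0])
        object.__setattr__(self, "bins", tuple(b))
        ss = [s for _, _, s in b]
        for lo, hi, s in b:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"{self.test_id}: malformed bin ({lo}, {hi}, {s})")
            if not (1 <= s <= 19):
                raise ValueError(f"{self.test_id}: scaled score {s} outside 1..19")
        for (_, hi, _), (lo2, _, _) in zip(b, b[1:]):
            if lo2 <= hi:
                raise ValueError(f"{self.test_id}: overlapping bins at raw {hi}")
        expect = sorted(ss) if self.direction == HIGHER else sorted(ss, reverse=True)
        if ss != expect:
            raise ValueError(f"{self.test_id}: scaled scores not monotone in raw")

    @property
    def raw_min(self) -> float:
        return self.bins[0][0]

    @property
    def raw_max(self) -> float:
        return self.bins[-1][1]

    @property
    def scaled_values(self) -> tuple[int, ...]:
        """Scaled scores available in this table, ascending."""
        return tuple(sorted(s for _, _, s in self.bins))

    def bin_for_scaled(self, scaled: int) -> tuple[float, float]:
        for lo, hi, s in self.bins:
            if s == scaled:
                return lo, hi
        raise KeyError(f"{self.test_id}: no bin for scaled score {scaled}")

    def to_dict(self) -> dict:
        return {
            "test_id": self.test_id,
            "direction": self.direction,
            "units": self.units,
            "bins": [{"lo": lo, "hi": hi, "ss": s} for lo, hi, s in self.bins],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormLookupTable":
        return cls(
            test_id=d["test_id"],
            direction=d["direction"],
            units=d["units"],
            bins=tuple((b["lo"], b["hi"], b["ss"]) for b in d["bins"]),
        )


def load_norm_tables(path=None) -> dict[str, NormLookupTable]:
    """Load a table set from JSON; defaults to the packaged Cameroonian tables."""
    if path is None:
        text = (
            resources.files("npnorm") / "data" / "cameroon_2020_scaled.json"
        ).read_text()
    else:
        with open(path, encoding="utf-8") as f:
            text = f.read()
    doc = json.loads(text)
    return {t["test_id"]: NormLookupTable.from_dict(t) for t in doc["tables"]}


def save_norm_tables(tables: dict[str, NormLookupTable], path, name="norm_tables"):
    doc = {"name": name, "tables": [t.to_dict() for t in tables.values()]}
    with open(path, "w", encoding="utf-8") as f:
        json.dump(doc, f, indent=1)


def raw_to_scaled(
    table: NormLookupTable, raw: float, warnings: list | None = None
) -> int:
    """Convert one raw score to its scaled score (integer 1-19).

    Out-of-range raws clamp to the nearest extreme scaled score; a record
    is appended to ``warnings`` (if given) instead of raising.
    """
    raw = float(raw)
    if not np.isfinite(raw):
        raise ValueError(f"{table.test_id}: non-finite raw score {raw}")
    los = [lo for lo, _, _ in table.bins]
    if raw < table.raw_min:
        idx = 0
        _warn(warnings, table.test_id, raw, "below")
    elif raw > table.raw_max:
        idx = len(table.bins) - 1
        _warn(warnings, table.test_id, raw, "above")
    else:
        idx = int(np.searchsorted(los, raw, side="right")) - 1
    return table.bins[idx][2]


def _warn(warnings, test_id, raw, side):
    if warnings is not None:
        warnings.append(
            {
                "test_id": test_id,
                "raw": raw,
                "issue": f"raw score {side} table range; clamped to extreme scaled score",
            }
        )


def raw_to_scaled_array(table: NormLookupTable, raw: np.ndarray) -> np.ndarray:
    """Vectorised lookup; NaN propagates, out-of-range clamps silently
    (use :func:`raw_to_scaled` for per-subject warning records)."""
    raw = np.asarray(raw, dtype=float)
    los = np.array([lo for lo, _, _ in table.bins])
    ss = np.array([s for _, _, s in table.bins], dtype=float)
    idx = np.clip(np.searchsorted(los, raw, side="right") - 1, 0, len(ss) - 1)
    out = ss[idx]
    out[~np.isfinite(raw)] = np.nan
    return out


def build_scaled_table(
    raw_scores: Sequence[float],
    direction: str,
    test_id: str,
    units: str = "count",
    min_n: int = 50,
    warnings: list | None = None,
) -> NormLookupTable:
    """Construct a scaled-score table from a normative sample.

    Rank normalisation: fractional (Hazen) rank r_i = (rank - 0.5)/n with
    mid-ranks for ties, oriented so better performance gets higher rank;
    z_i the standard-normal quantile of r_i; scaled_i = round(10 + 3 z_i)
    clipped to [1, 19]. Bins are the contiguous raw ranges sharing a scaled
    value, with edges extended halfway into the gaps between neighbouring
    groups so the table covers the whole observed range.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("raw scores must be a flat array of finite numbers")
    if len(x) < min_n:
        raise ValueError(f"normative sample too small: n={len(x)} < {min_n}")
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"bad direction {direction!r}")
    perf = x if direction == HIGHER else -x
    if np.ptp(x) == 0:
        if warnings is not None:
            warnings.append(
                {"test_id": test_id, "issue": "all raw scores identical; single bin"}
            )
        return NormLookupTable(test_id, direction, units, ((x[0], x[0], 10),))
    r = (rankdata(perf, method="average") - 0.5) / len(x)
    z = ndtri(r)
    scaled = np.clip(np.rint(10 + 3 * z), 1, 19).astype(int)

    # group raw values by scaled score, ascending in raw
    order = np.argsort(x, kind="stable")
    xs, ssx = x[order], scaled[order]
    bins = []
    lo = xs[0]
    for k in range(1, len(xs) + 1):
        if k == len(xs) or ssx[k] != ssx[k - 1]:
            hi = xs[k - 1]
            bins.append([lo, hi, int(ssx[k - 1])])
            if k < len(xs):
                lo = xs[k]
    # extend edges to midpoints so the covered raw range is contiguous
    for a, b in zip(bins, bins[1:]):
        mid = 0.5 * (a[1] + b[0])
        a[1] = mid
        b[0] = np.nextafter(mid, np.inf)
    return NormLookupTable(
        test_id, direction, units, tuple((lo, hi, s) for lo, hi, s in bins)
    )
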