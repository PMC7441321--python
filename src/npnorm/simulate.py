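"""Synthetic case-control cohort generator.

Emulates the demographic and clinical structure of the norming study
cohort (683 Cameroonian adults: 363 HIV- controls, 320 HIV+ cases):
truncated-normal integer age and education per group, Bernoulli sex,
log-normal CD4 matched to the published median/IQR, detectable viral load
with the published probability, and ART status proportions.

Test scores are generated on the latent scaled-score scale: each
subject's expected scaled score comes from the shipped normative
formulas, HIV/ART/CD4/VL effects are injected as Cohen's d shifts on the
T scale (1 d = one residual SD on the scaled scale), Gaussian noise with
the test's residual SD is added, the result is rounded and clipped to
the scaled scores available in the conversion table, and the raw score is
drawn uniformly from the table bin for that scaled score (integer raw
units, matching the published tables).

Subgroup effects (ART, CD4, VL) are mean-centred within the case group
using their configured prevalences, so the configured HIV effect remains
the marginal case-control Cohen's d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .norm_tables import NormLookupTable, load_norm_tables
from .registry import TESTS
from .tscore import TScoreFormula, load_tscore_formulas

# marginal case-control Cohen's d per test (negative = cases worse)
DEFAULT_HIV_EFFECTS = {
    "gp_dh": -0.18, "gp_ndh": -0.10,
    "wais_ds": -0.25, "wais_ss": -0.03, "stroop_color": -0.09,
    "stroop_word": -0.19, "tmt_a": -0.18, "ctt1": -0.13,
}


@dataclass(frozen=True)
class GroupDemographics:
    n: int
    age_mean: float
    age_sd: float
    age_range: tuple[int, int]
    edu_mean: float
    edu_sd: float
    edu_range: tuple[int, int]
    male_p: float


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic cohort."""

    controls: GroupDemographics = GroupDemographics(
        n=363, age_mean=34.3, age_sd=10.6, age_range=(18, 64),
        edu_mean=12.4, edu_sd=4.2, edu_range=(0, 21), male_p=0.344,
    )
    cases: GroupDemographics = GroupDemographics(
        n=320, age_mean=37.8, age_sd=9.4, age_range=(18, 60),
        edu_mean=9.6, edu_sd=3.7, edu_range=(2, 20), male_p=0.222,
    )
    hiv_effects: dict = field(default_factory=lambda: dict(DEFAULT_HIV_EFFECTS))
    art_effect_d: float = 0.24     # on-ART vs not, SIP-summary-scale d
    cd4_effect_d: float = 0.22     # CD4 >= 350 vs < 350
    vl_effect_d: float = 0.0       # detectable vs undetectable (none observed)
    art_p: tuple[float, float, float] = (0.536, 0.445, 0.019)  # on-ART, naive, other
    cd4_median: float = 405.0
    cd4_log_sigma: float = math.log(574 / 246) / (2 * 0.6744897501960817)
    vl_detectable_p: float = 0.428
    log10_vl_mean: float = 4.61
    log10_vl_sd: float = 1.30
    demographic_scale: float = 1.0  # 0 removes demographic effects on scores
    noise_scale: float = 1.0        # multiplier on per-test residual SD
    right_handed_p: float = 0.9
    seed: int = 0

    def validate(self):
        for g in (self.controls, self.cases):
            for m, s, (lo, hi) in ((g.age_mean, g.age_sd, g.age_range),
                                   (g.edu_mean, g.edu_sd, g.edu_range)):
                if m < lo - 5 * s or m > hi + 5 * s:
                    raise ValueError("infeasible config: truncation bounds exclude "
                                     "the mean by more than 5 SD")
            if not 0 <= g.male_p <= 1:
                raise ValueError("male_p must be in [0, 1]")
        if abs(sum(self.art_p) - 1) > 1e-9:
            raise ValueError("ART status proportions must sum to 1")


def _trunc_normal_int(rng, n, mean, sd, lo, hi):
    """Integer truncated normal by redrawing out-of-range values."""
    out = np.empty(n)
    todo = np.arange(n)
    while len(todo):
        draw = rng.normal(mean, sd, size=len(todo))
        ok = (draw >= lo - 0.5) & (draw <= hi + 0.5)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.clip(np.rint(out), lo, hi).astype(int)


def _invert_table(rng, table: NormLookupTable, latent_ss: np.ndarray) -> np.ndarray:
    """Integer raw score drawn uniformly from the bin of each scaled score."""
    avail = np.array(table.scaled_values)
    ss = np.clip(np.rint(latent_ss), avail.min(), avail.max()).astype(int)
    raw = np.empty(len(ss), dtype=int)
    for s in np.unique(ss):
        lo, hi = table.bin_for_scaled(int(s))
        m = ss == s
        raw[m] = rng.integers(int(math.ceil(lo)), int(math.floor(hi)) + 1, size=m.sum())
    return raw


COLUMNS = (
    ["id", "group", "age", "edu", "sex", "male", "hand"]
    + [f"{t}_raw" for t in TESTS]
    + ["cd4", "vl_detectable", "log10_vl", "art_status"]
)


def generate_cohort(
    config: SimConfig = SimConfig(),
    tables: dict[str, NormLookupTable] | None = None,
    formulas: dict[str, TScoreFormula] | None = None,
) -> pd.DataFrame:
    """Generate a synthetic cohort; fixed seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tables = tables if tables is not None else load_norm_tables()
    formulas = formulas if formulas is not None else load_tscore_formulas()

    frames = []
    for group, g in (("HIV-", config.controls), ("HIV+", config.cases)):
        n = g.n
        age = _trunc_normal_int(rng, n, g.age_mean, g.age_sd, *g.age_range)
        edu = _trunc_normal_int(rng, n, g.edu_mean, g.edu_sd, *g.edu_range)
        male = (rng.random(n) < g.male_p).astype(int)
        hand = np.where(rng.random(n) < config.right_handed_p, "right", "left")
        df = pd.DataFrame(
            {"group": group, "age": age, "edu": edu,
             "sex": np.where(male == 1, "male", "female"), "male": male,
             "hand": hand}
        )
        if group == "HIV+":
            df["cd4"] = np.rint(
                np.exp(rng.normal(math.log(config.cd4_median), config.cd4_log_sigma, n))
            ).astype(int)
            det = rng.random(n) < config.vl_detectable_p
            df["vl_detectable"] = det.astype(int)
            lvl = rng.normal(config.log10_vl_mean, config.log10_vl_sd, n)
            df["log10_vl"] = np.where(det, np.round(np.maximum(lvl, 0.0), 2), np.nan)
            df["art_status"] = rng.choice(
                ["on-ART", "naive", "other"], size=n, p=list(config.art_p)
            )
        else:
            df["cd4"] = np.nan
            df["vl_detectable"] = np.nan
            df["log10_vl"] = np.nan
            df["art_status"] = ""
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "id", [f"S{i:04d}" for i in range(1, len(cohort) + 1)])

    case = (cohort["group"] == "HIV+").to_numpy()
    on_art = (cohort["art_status"] == "on-ART").to_numpy()
    cd4_hi = (cohort["cd4"].to_numpy(dtype=float) >= 350) & case
    detectable = cohort["vl_detectable"].fillna(0).to_numpy(dtype=float) > 0
    p_art = config.art_p[0]
    # theoretical P(CD4 >= 350) under the configured log-normal
    from scipy.stats import norm as _norm
    p_cd4 = float(
        _norm.sf((math.log(350) - math.log(config.cd4_median)) / config.cd4_log_sigma)
    )
    p_vl = config.vl_detectable_p

    # T-scale subgroup shifts, mean-centred within cases (in d units)
    subgroup_d = np.zeros(len(cohort))
    subgroup_d[case & on_art] += config.art_effect_d * (1 - p_art)
    subgroup_d[case & ~on_art] -= config.art_effect_d * p_art
    subgroup_d[case & cd4_hi] += config.cd4_effect_d * (1 - p_cd4)
    subgroup_d[case & ~cd4_hi] -= config.cd4_effect_d * p_cd4
    subgroup_d[case & detectable] += config.vl_effect_d * (1 - p_vl)
    subgroup_d[case & ~detectable] -= config.vl_effect_d * p_vl

    ref_age, ref_edu, ref_male = 35.0, 12.0, 0.0
    for tid in TESTS:
        f = formulas[tid]
        pred = f.predicted(cohort["age"], cohort["edu"], cohort["male"])
        ref = float(f.predicted(ref_age, ref_edu, ref_male))
        latent = ref + config.demographic_scale * (pred - ref)
        d_shift = np.where(case, config.hiv_effects.get(tid, 0.0), 0.0) + subgroup_d
        latent = latent + d_shift * f.residual_sd
        latent = latent + rng.normal(0.0, config.noise_scale * f.residual_sd, len(cohort))
        cohort[f"{tid}_raw"] = _invert_table(rng, tables[tid], latent)
    return cohort[COLUMNS]


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-loaded) nested dict.

    Top-level keys mirror the dataclass fields; ``controls`` and ``cases``
    are nested dicts of GroupDemographics fields. Missing keys keep the
    study-condition defaults.
    """
    d = dict(d or {})
    kwargs = {}
    for grp in ("controls", "cases"):
        if grp in d:
            sub = d.pop(grp)
            base = getattr(SimConfig(), grp)
            fields = {k: sub.get(k, getattr(base, k)) for k in (
                "n", "age_mean", "age_sd", "age_range", "edu_mean", "edu_sd",
                "edu_range", "male_p")}
            for k in ("age_range", "edu_range"):
                fields[k] = tuple(fields[k])
            kwargs[grp] = GroupDemographics(**fields)
    if "art_p" in d:
        d["art_p"] = tuple(d["art_p"])
    kwargs.update(d)
    return SimConfig(**kwargs)


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the documented column order.

    Integer-valued nullable columns are serialized without decimal points
    so that write -> read -> write round-trips byte-identically.
    """
    df = records.copy()
    for col in ("cd4", "vl_detectable"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    cols = [c for c in COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in COLUMNS
    ]
    df[cols].to_csv(path, index=False, lineterminator="\n")
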