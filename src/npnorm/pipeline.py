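"""End-to-end pipeline: read -> score -> classify -> analyze.

Deterministic with respect to its inputs; every stage logs counts to
stderr and the run returns a machine-readable summary. Outputs are a
scored/classified CSV and an analysis report mirroring the study's table
layout (per-test and summary T comparisons with Cohen's d, CI, raw and
FDR-adjusted p; impairment counts, percentages and odds ratios).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis as ga
from .deficit import classify_dataframe
from .io import read_subjects
from .norm_tables import load_norm_tables
from .registry import TESTS
from .tscore import load_tscore_formulas, score_dataframe

log = logging.getLogger("npnorm")


@dataclass
class PipelineConfig:
    norm_tables_path: str | None = None   # None = packaged Cameroonian tables
    formulas_path: str | None = None
    groupings: tuple[str, ...] = ("hiv",)
    round_t: int = 1


def _comparison_table(results):
    return [r.rounded() for r in results]


def run_pipeline(config: PipelineConfig, input_path, scored_out=None, report_out=None):
    """Run the full scoring pipeline on a subject CSV.

    Returns ``(scored_frame, report_dict)``; optionally writes the scored
    CSV and JSON report. Re-running on identical inputs yields identical
    outputs.
    """
    tables = load_norm_tables(config.norm_tables_path)
    formulas = load_tscore_formulas(config.formulas_path)

    subjects, warnings = read_subjects(input_path)
    if len(subjects) == 0:
        warnings.append({"row": None, "id": None, "issue": "empty input: no subject rows"})
    log.info("read %d subjects (%d validation warnings)", len(subjects), len(warnings))

    scored = score_dataframe(subjects, tables, formulas)
    log.info("scored %d subjects on %d tests", len(scored),
             sum(f"{t}_t" in scored.columns for t in TESTS))
    classified = classify_dataframe(scored)
    log.info("classified %d subjects", len(classified))

    report = {
        "n_subjects": len(subjects),
        "n_warnings": len(warnings),
        "warnings": warnings,
        "t_comparisons": {},
        "impairment": {},
    }
    if len(classified) and set(classified["group"]) >= {"HIV-", "HIV+"}:
        for grouping in config.groupings:
            try:
                res = ga.subgroup_compare(classified, grouping)
            except (ValueError, KeyError) as e:
                log.warning("grouping %s skipped: %s", grouping, e)
                continue
            report["t_comparisons"][grouping] = _comparison_table(res)
        imp = ga.impairment_compare(classified)
        report["impairment"]["hiv"] = _comparison_table(imp)
        # impairment prevalence per group and measure
        prev = {}
        for col in [f"{t}_impaired" for t in TESTS] + ["motor_impaired", "sip_impaired"]:
            if col not in classified.columns:
                continue
            prev[col] = {
                g: {
                    "n": int(classified.loc[classified["group"] == g, col].notna().sum()),
                    "impaired": int(classified.loc[classified["group"] == g, col].sum(skipna=True) or 0),
                }
                for g in ("HIV-", "HIV+")
            }
        report["impairment"]["prevalence"] = prev
    else:
        log.warning("no case/control structure in input; analysis skipped")

    if scored_out is not None:
        out = classified.copy()
        tcols = [c for c in out.columns if c.endswith("_t") or c.endswith("_dds")]
        out[tcols] = out[tcols].round(config.round_t)
        out.to_csv(scored_out, index=False, lineterminator="\n")
        log.info("wrote scored CSV: %s", scored_out)
    if report_out is not None:
        with open(report_out, "w", encoding="utf-8") as f:
            json.dump(report, f, indent=1, default=_json_default)
        log.info("wrote report: %s", report_out)
    return classified, report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if o is pd.NA:
        return None
    raise TypeError(f"not JSON serializable: {type(o)}")
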