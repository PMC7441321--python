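#!/usr/bin/env python
"""Recompute every statistic that is a deterministic function of the
published group-level inputs: odds ratios and Wald CIs from the published
impairment counts, impairment percentages, Cohen's d from the published
means/SDs/Ns, and BH-adjusted p-values from the published raw p-values
with the study's family sizes."""

import argparse
import json
from pathlib import Path

import pandas as pd

from npnorm import bh_adjust, cohens_d, odds_ratio
from npnorm.published import (
    IMPAIRMENT_SUMMARY, SUMMARY_ROWS, TEST_ROWS, TSCORE_SUMMARY,
)

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=Path, default=Path("results/printed_reproduction.json"))
args = ap.parse_args()

doc = {"cohens_d": {}, "odds_ratio": {}, "impaired_pct": {}, "bh_adjusted_p": {}}

adj8 = dict(zip(TEST_ROWS, bh_adjust([TSCORE_SUMMARY[t]["p"] for t in TEST_ROWS], k=8)))
adj2 = dict(zip(SUMMARY_ROWS, bh_adjust([TSCORE_SUMMARY[t]["p"] for t in SUMMARY_ROWS], k=2)))
rows = []
for t in TEST_ROWS + SUMMARY_ROWS:
    s = TSCORE_SUMMARY[t]
    d = cohens_d(s["mean"][0], s["sd"][0], s["n"][0], s["mean"][1], s["sd"][1], s["n"][1])
    i = IMPAIRMENT_SUMMARY[t]
    orr = odds_ratio(i["impaired"][0], i["n"][0], i["impaired"][1], i["n"][1])
    adj = (adj8 | adj2)[t]
    doc["cohens_d"][t] = round(d.estimate, 2)
    doc["odds_ratio"][t] = [round(orr.estimate, 2), round(orr.ci_low, 2), round(orr.ci_high, 2)]
    doc["impaired_pct"][t] = [round(100 * i["impaired"][0] / i["n"][0], 1),
                              round(100 * i["impaired"][1] / i["n"][1], 1)]
    doc["bh_adjusted_p"][t] = round(adj, 3)
    rows.append({
        "measure": t, "d": doc["cohens_d"][t],
        "OR": doc["odds_ratio"][t][0],
        "OR_ci": f"({doc['odds_ratio'][t][1]}, {doc['odds_ratio'][t][2]})",
        "impaired_ctrl_pct": doc["impaired_pct"][t][0],
        "impaired_case_pct": doc["impaired_pct"][t][1],
        "raw_p": TSCORE_SUMMARY[t]["p"], "adj_p": doc["bh_adjusted_p"][t],
    })

args.out.parent.mkdir(parents=True, exist_ok=True)
with open(args.out, "w") as f:
    json.dump(doc, f, indent=1)
print(pd.DataFrame(rows).to_string(index=False))
print(f"\nwrote {args.out}")
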