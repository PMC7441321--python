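#!/usr/bin/env python
"""Score the cohort with the published tables and formulas (raw -> scaled
-> T -> domain summaries), classify deficits and impairment, and report
the control-group calibration: controls should centre at T = 50, SD = 10,
with per-test impairment near 16%."""

import argparse
from pathlib import Path

from npnorm import TESTS, read_subjects, score_dataframe
from npnorm.deficit import classify_dataframe

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
ap.add_argument("--out", type=Path, default=Path("results/scored.csv"))
args = ap.parse_args()

df, warnings = read_subjects(args.cohort)
scored = classify_dataframe(score_dataframe(df))
args.out.parent.mkdir(parents=True, exist_ok=True)
scored.to_csv(args.out, index=False, lineterminator="\n")

ctrl = scored[scored.group == "HIV-"]
print(f"{len(scored)} subjects scored ({len(warnings)} input warnings)\n")
print("control-group calibration (expect mean ~50, SD ~10):")
for tid in TESTS:
    t = ctrl[f"{tid}_t"]
    imp = 100 * ctrl[f"{tid}_impaired"].mean()
    print(f"  {tid:13s} T {t.mean():5.1f} ({t.std():4.1f})  impaired {imp:4.1f}%")
for dom in ("motor", "sip"):
    t = ctrl[f"{dom}_t"]
    imp = 100 * ctrl[f"{dom}_impaired"].mean()
    print(f"  {dom + '_summary':13s} T {t.mean():5.1f} ({t.std():4.1f})  impaired {imp:4.1f}%")
print(f"\nwrote {args.out}")
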