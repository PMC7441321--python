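#!/usr/bin/env python
"""Generate the default synthetic case-control cohort (363 HIV- controls,
320 HIV+ cases with study-matched demographics and effect sizes) and save
it for the downstream analysis steps."""

import argparse
from pathlib import Path

from npnorm import SimConfig, generate_cohort, write_cohort
from dataclasses import replace

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--out", type=Path, default=Path("results/cohort.csv"))
args = ap.parse_args()

cohort = generate_cohort(replace(SimConfig(), seed=args.seed))
args.out.parent.mkdir(parents=True, exist_ok=True)
write_cohort(cohort, args.out)

for grp, g in cohort.groupby("group"):
    print(
        f"{grp}: n={len(g)}, age {g.age.mean():.1f} ({g.age.std():.1f}), "
        f"edu {g.edu.mean():.1f} ({g.edu.std():.1f}), "
        f"male {100 * g.male.mean():.1f}%"
    )
case = cohort[cohort.group == "HIV+"]
print(
    f"cases: CD4 median {case.cd4.median():.0f}, "
    f"detectable VL {100 * case.vl_detectable.mean():.1f}%, "
    f"on ART {100 * (case.art_status == 'on-ART').mean():.1f}%"
)
print(f"wrote {args.out}")
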