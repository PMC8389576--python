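#!/usr/bin/env python
"""Cytotype × photoperiod comparison per coefficient.

Two-way Type II ANOVA, then Tukey HSD for the quantum yields and Duncan's
multiple range test for everything else (the figure-default mapping), each
summarized as a compact letter display over the 8 design cells.

    python analysis/03_group_statistics.py [--run scratch/study]
"""

import argparse
import json
from pathlib import Path

from pamflux.io import read_coefficients
from pamflux.pipeline import PipelineConfig, run_statistics

ap = argparse.ArgumentParser()
ap.add_argument("--run", type=Path, default=Path("scratch/study"))
ap.add_argument("--alpha", type=float, default=0.05)
args = ap.parse_args()

table = read_coefficients(args.run / "coefficients.csv")
results = run_statistics(table, PipelineConfig(alpha=args.alpha))
out = args.run / "stats.json"
out.write_text(json.dumps(results, indent=2, sort_keys=True), encoding="utf-8")

print(f"analyzed {len(results)} coefficients -> {out}\n")
print(f"{'coefficient':<12} {'method':<7} {'p(cyto)':>9}  letters (cell: letter)")
for coef, res in sorted(results.items()):
    p = next(r["p"] for r in res["anova"]["table"] if r["term"] == "cytotype")
    letters = res["posthoc"]["letters"]
    compact = " ".join(f"{c}:{letters[c]}" for c in sorted(letters))
    print(f"{coef:<12} {res['posthoc']['method']:<7} {p:>9.2g}  {compact}")
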