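#!/usr/bin/env python
"""Landmarks → per-plant coefficients.

Reads the traces written by 01_simulate_study.py, extracts F0/FM/FM′/F(t)/
FM″ (Kautsky), the per-step (F(t), FM′) pairs (light curve) and the O/J/I/P
levels (fast transient), and computes the full coefficient table:
ϕ_max, ϕ_PSII, NPQ, qE, qI, qP, qL, PQ, rETR per PPFD step, and the
JIP-test fluxes.  Failed plants are reported by id.

    python analysis/02_compute_coefficients.py [--run scratch/study]
"""

import argparse
from pathlib import Path

from pamflux.io import read_trace, write_coefficients
from pamflux.pipeline import PipelineConfig, compute_coefficient_table
from pamflux.simulate import GroupFactor, StudyData

ap = argparse.ArgumentParser()
ap.add_argument("--run", type=Path, default=Path("scratch/study"))
args = ap.parse_args()

traces: dict[str, dict] = {}
for tsv in sorted((args.run / "traces").glob("*.tsv")):
    trace = read_trace(tsv)
    traces.setdefault(trace.meta["plant_id"], {})[trace.protocol_id] = trace
design = [(pid, GroupFactor(t["KC"].meta["cytotype"],
                            float(t["KC"].meta["photoperiod_h"])))
          for pid, t in traces.items()]
study = StudyData(design=design, traces=traces, ground_truth=None)

table, failures, tallies = compute_coefficient_table(study, PipelineConfig())
out = args.run / "coefficients.csv"
write_coefficients(table, out)

print(f"{len(design)} plants -> {len(table)} coefficient rows -> {out}")
if failures:
    print(f"FAILED plants ({len(failures)}):")
    for f in failures:
        print(" ", f)
else:
    print("no extraction failures")
print(f"warnings: {tallies}")
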