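#!/usr/bin/env python
"""Spontaneous-activity analysis: bleach correction, events, synchrony.

Runs the full spontaneous pipeline on the coupled trace set from
01_simulate_datasets.py, then sweeps the shared-event fraction to show that
the zero-lag correlation coefficient tracks the degree of event coupling.
Writes results/spontaneous/ (pipeline tables) and
results/synchrony_vs_coupling.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from wormquant import io as wio
from wormquant import synth
from wormquant.events import cross_correlate
from wormquant.pipelines import SpontaneousRunConfig, run_spontaneous_pipeline
from wormquant.traces import correct_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = SpontaneousRunConfig(
    traces_csv=str(args.data / "coupled_traces.csv"),
    out_dir=str(args.out / "spontaneous"))
report = run_spontaneous_pipeline(cfg)
stats = wio.read_table(args.out / "spontaneous" / "stats.tsv", sep="\t")
truth = pd.read_csv(args.data / "coupled_truth.tsv", sep="\t", comment="#")
print("per-neuron event frequency (true rate 2.0 per min):")
for row in stats.itertuples():
    n_true = (truth["trace_id"] == row.roi).sum()
    print(f"  {row.roi}: {row.frequency_per_min:.2f} per min "
          f"({row.n_events} detected, {n_true} injected)")
xc = wio.read_table(args.out / "spontaneous" / "xcorr.csv")
print("pairwise zero-lag r (half of events shared):")
for row in xc.itertuples():
    print(f"  {row.roi_a} vs {row.roi_b}: r0 = {row.r0:.3f}")

# synchrony as a function of the shared-event fraction, 20 pairs per level
rows = []
for i, sf in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
    r0s = []
    for k in range(20):
        traces, _ = synth.generate_coupled(
            synth.SpontaneousConfig(seed=args.seed + 1000 + 100 * i + k),
            synth.CouplingConfig(shared_fraction=sf))
        nts = [correct_pipeline(t) for t in traces]
        r0s.append(cross_correlate(nts[0], nts[1]).r0)
    rows.append({"shared_fraction": sf, "mean_r0": np.mean(r0s),
                 "sd_r0": np.std(r0s, ddof=1), "n_pairs": len(r0s)})
tab = pd.DataFrame(rows)
wio.write_table(args.out / "synchrony_vs_coupling.csv", tab,
                stage="analysis", params={"seed": args.seed})
print("mean r0 by shared fraction:")
print(tab.to_string(index=False))
assert tab["mean_r0"].is_monotonic_increasing, \
    "synchrony should rise with coupling"
print("zero-lag correlation increases monotonically with event coupling")
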