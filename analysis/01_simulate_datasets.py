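#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes, under results/data/:
  coupled_traces.csv / coupled_truth.tsv   — 3 neurons, half-shared events
  naive.csv, trained.csv                   — evoked Ca²⁺-drop groups
                                             (naïve -0.6 ΔF/F0 for 60 s,
                                             trained -0.3 ΔF/F0 for 30 s)
  assay_counts.csv                         — choice-assay counts, naïve
                                             (p_PA14 = 0.8) vs trained (0.3)
  speed_learning.csv                       — two genotype-like groups with
                                             different speed–learning slopes
  dose_response.csv                        — histamine dose vs speed, 4PL
                                             with IC50 = 5 mM, 5% noise
  junction_sweeps/                         — Vj-step current sweeps,
                                             g_anti/g_ortho = 10
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from wormquant import io as wio
from wormquant import synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()
out = args.out

# spontaneous coupled set
cfg = synth.SpontaneousConfig(seed=args.seed)
traces, truth = synth.generate_coupled(
    cfg, synth.CouplingConfig(n_neurons=3, shared_fraction=0.5))
wio.write_traces_csv(out / "coupled_traces.csv", traces, params=asdict(cfg))
wio.write_truth_tsv(out / "coupled_truth.tsv", truth)
print(f"coupled set: 3 neurons, "
      f"{sum(len(v) for v in truth.events.values())} true events")

# evoked groups
for name, amp, dur in (("naive", -0.6, 60.0), ("trained", -0.3, 30.0)):
    group = []
    for i in range(8):
        raw, _ = synth.generate_evoked(synth.EvokedConfig(
            drop_amp=amp, drop_dur_s=dur, recovery_shape="linear",
            recovery_s=10, duration_s=150, noise_sd=0.02,
            seed=args.seed + 100 + i))
        raw.roi_label = f"animal_{i}"
        group.append(raw)
    wio.write_traces_csv(out / f"{name}.csv", group)
    print(f"{name} evoked group: 8 animals, drop {amp} for {dur:g} s")

# choice assays (5 plates per condition)
rows = []
for plate in range(5):
    for cond, p in (("naive", 0.8), ("trained", 0.3)):
        c = synth.generate_choice_counts(synth.AssayConfig(
            n_animals=120, p_pa14=p, seed=args.seed + 200 + 10 * plate
            + (0 if cond == "naive" else 1)))
        rows.append({"plate_id": plate, "condition": cond,
                     "n_test": c.n_pa14, "n_ref": c.n_op50})
wio.write_table(out / "assay_counts.csv", pd.DataFrame(rows),
                stage="simulate")
print("choice assays: 5 plates x 2 conditions, 120 animals each")

# speed-learning point clouds: wild-type-like slope vs a flattened one
speeds = np.linspace(50, 250, 30)
rows = []
for group, slope in (("control", 0.004), ("proprioception_defective", 0.001)):
    for p in synth.generate_speed_learning(slope, 0.1, 0.1, speeds,
                                           seed=args.seed + 300
                                           + (0 if group == "control"
                                              else 1)):
        rows.append({"group": group, "speed": p.speed,
                     "learning_index": p.learning_index})
wio.write_table(out / "speed_learning.csv", pd.DataFrame(rows),
                stage="simulate")
print("speed-learning clouds: 30 points per group")

# histamine dose-response of locomotion speed
doses = np.array([0.0, 0.5, 1, 2, 5, 10, 20, 50])
clean = synth.hill_response(doses, top=150, bottom=20, ic50=5, hill=1.5)
rng = np.random.default_rng(args.seed + 400)
wio.write_table(out / "dose_response.csv",
                pd.DataFrame({"dose_mM": doses,
                              "response": np.clip(
                                  clean * (1 + rng.normal(0, 0.05,
                                                          doses.size)),
                                  0, None)}),
                stage="simulate")
print("dose-response: 8 doses, IC50 truth 5 mM")

# junction sweeps
jcfg = synth.JunctionConfig(g_anti_nS=1.0, g_ortho_nS=0.1, noise_pA=0.5,
                            seed=args.seed + 500)
sweeps, jtruth = synth.generate_junction_sweeps(jcfg)
for sweep in sweeps:
    vj = sweep.windows[0].level
    tag = f"vj_{'m' if vj < 0 else 'p'}{abs(vj):g}"
    wio.write_table(out / "junction_sweeps" / f"sweep_{tag}.csv",
                    pd.DataFrame({"time_ms": sweep.time_ms,
                                  "signal": sweep.signal}),
                    stage="simulate", units="milliseconds",
                    params={"vj_mV": vj,
                            "onset_ms": sweep.windows[0].onset_ms,
                            "offset_ms": sweep.windows[0].offset_ms})
wio.write_yaml(out / "junction_truth.yaml", asdict(jtruth.junction))
print(f"junction sweeps: {len(sweeps)} Vj steps, "
      f"g_anti/g_ortho = {jcfg.g_anti_nS / jcfg.g_ortho_nS:g}")
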