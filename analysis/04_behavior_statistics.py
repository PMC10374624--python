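#!/usr/bin/env python
"""Behavioral statistics: indices, speed-dependence, dose-response.

From the tables written by 01_simulate_datasets.py: per-plate choice
indices and the learning index; linear speed–learning fits per group with
the extra-sum-of-squares F-test between them; the 4PL IC50 of the
histamine dose–response.  Writes results/behavior_*.tsv.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from wormquant import io as wio
from wormquant.behavior import (ChoiceCounts, SpeedLearningPoint,
                                choice_index, compare_fits, fit_ic50,
                                fit_line, learning_index)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

# choice and learning indices
assay = wio.read_table(args.data / "assay_counts.csv")
assay["choice_index"] = [
    choice_index(ChoiceCounts(int(r.n_test), int(r.n_ref)))
    for r in assay.itertuples()]
ci = assay.groupby("condition")["choice_index"].mean()
li = learning_index(ci["naive"], ci["trained"])
wio.write_table(args.out / "behavior_indices.tsv", assay, stage="analysis",
                sep="\t")
print(f"mean choice index: naive {ci['naive']:+.3f}, "
      f"trained {ci['trained']:+.3f}")
print(f"learning index (naive - trained): {li:+.3f} "
      "(positive = learned aversion to PA14)")

# speed-learning fits and comparison
sl = wio.read_table(args.data / "speed_learning.csv")
groups = sorted(sl["group"].unique())
points = {g: [SpeedLearningPoint(r.speed, r.learning_index)
              for r in sl[sl["group"] == g].itertuples()] for g in groups}
fits = {g: fit_line(points[g]) for g in groups}
for g, fit in fits.items():
    print(f"{g}: learning index = {fit.intercept:.3f} "
          f"+ {fit.slope:.5f} x speed (n={fit.n}, RSS={fit.rss:.3f})")
cmp_result = compare_fits(points[groups[0]], points[groups[1]])
print(f"fit comparison (shared vs separate lines): "
      f"F({cmp_result.df_num},{cmp_result.df_den}) = "
      f"{cmp_result.f_stat:.2f}, p = {cmp_result.p_value:.2e}")
rows = [{"group": g, **asdict(f)} for g, f in fits.items()]
rows.append({"group": f"{groups[0]} vs {groups[1]}",
             **asdict(cmp_result)})
wio.write_table(args.out / "behavior_speed_fits.tsv", pd.DataFrame(rows),
                stage="analysis", sep="\t")

# dose-response IC50
dr = wio.read_table(args.data / "dose_response.csv")
hill = fit_ic50(dr["dose_mM"].to_numpy(), dr["response"].to_numpy())
wio.write_table(args.out / "behavior_ic50.tsv",
                pd.DataFrame([asdict(hill)]), stage="analysis", sep="\t")
print(f"histamine dose-response: IC50 = {hill.ic50:.2f} mM "
      f"(truth 5 mM), Hill = {hill.hill:.2f}, R² = {hill.r_squared:.4f}")
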