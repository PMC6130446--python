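"""Heritability and shared environment of connectotype predictions.

Averages each pair's two comparison directions into one outcome vector,
rank-inverse-normal transforms per ROI, and partitions variance with the
sequential repeated-measures ANOVA (ROI -> shared environment -> shared
genetics), resampling a matched unrelated subset per ANOVA.  Reports
whole-brain and per-network h2/c2 with percentile CIs.

Run:  python analysis/05_heritability.py [--n-anovas 200]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from connectokin import pairs as prs
from connectokin.cohort_io import load_cohort, load_parcellation
from connectokin.heritability import estimate_all_levels, pair_outcomes_from_comparisons

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--n-anovas", type=int, default=200)
parser.add_argument("--match-n", type=int, default=40)
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

cohort = load_cohort(args.data / "roster.tsv", args.data / "zygosity.tsv")
parc = load_parcellation(args.data / "parcellation.tsv")
tab = pd.read_csv(args.out / "comparisons.tsv", sep="\t")
per_roi = np.loadtxt(args.out / "comparisons_per_roi.tsv", delimiter="\t")
results = prs.ComparisonResults(table=tab, per_roi=per_roi)

outcomes = pair_outcomes_from_comparisons(results, cohort)
n_unrel = int((outcomes.genetics == "unrelated").sum())
match_n = min(args.match_n, n_unrel)
print(f"{len(outcomes.genetics)} pairs "
      f"({(outcomes.genetics == 'MZ').sum()} MZ, "
      f"{(outcomes.genetics == 'DZ_or_sib').sum()} DZ/sib, {n_unrel} unrelated); "
      f"matching {match_n} unrelated per ANOVA")

table = estimate_all_levels(outcomes, parcellation=parc,
                            n_unrelated_match=match_n,
                            n_anovas=args.n_anovas, seed=args.seed)
table.to_csv(args.out / "heritability.tsv", sep="\t", index=False)

wb = table[table["kind"] == "whole_brain"].iloc[0]
print(f"whole-brain h2 = {wb['h2']:.3f} (95% CI {wb['h2_lo']:.3f}-{wb['h2_hi']:.3f})")
print(f"whole-brain c2 = {wb['c2']:.3f} (95% CI {wb['c2_lo']:.3f}-{wb['c2_hi']:.3f})")
nets = table[table["kind"] == "network"].sort_values("h2", ascending=False)
print("networks by h2:")
for _, row in nets.head(6).iterrows():
    print(f"  {row['level']:32s} h2={row['h2']:.3f} c2={row['c2']:.3f}")
rois = table[table["kind"] == "roi"]
sig = (rois["p_genetics_corrected"] < 0.05).sum()
print(f"{sig}/{len(rois)} ROIs with corrected p < 0.05 for shared genetics")
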