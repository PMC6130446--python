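"""Fingerprinting and familiality of the connectotype.

Loads the simulated cohort, preprocesses every scan (AR(1) prewhitening),
fits one connectotype per scan, and scores every ordered scan-pair
comparison.  Reports the group similarity distributions (self same-scan /
self other-scan / MZ / DZ / sibling / unrelated), the sibling-vs-unrelated
contrast after Fisher z, and — for the youth-style roster — the printed
pair-enumeration bookkeeping (188^2 = 35,344 comparisons: 188 + 60 + 46 +
35,050).

Run:  python analysis/02_fingerprinting.py
"""

import argparse
import json
from pathlib import Path

from connectokin import pairs as prs
from connectokin.cohort_io import load_cohort, load_parcellation, load_timeseries, load_fd
from connectokin.preprocess import PreprocessConfig, preprocess_scan

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = load_cohort(args.data / "roster.tsv", args.data / "zygosity.tsv")
parc = load_parcellation(args.data / "parcellation.tsv")
cfg = PreprocessConfig(profile="custom", do_censor=False, do_filter=False,
                       ar_order=1)
residuals = {}
for sid in cohort.scans["scan_id"]:
    ts = load_timeseries(args.data / "timeseries" / f"{sid}.tsv", parc,
                         tr=2.5, scan_id=sid)
    residuals[sid], _ = preprocess_scan(ts, cfg=cfg)

results = prs.run_all_comparisons(cohort, residuals)
results.table.to_csv(args.out / "comparisons.tsv", sep="\t", index=False)
import numpy as np
np.savetxt(args.out / "comparisons_per_roi.tsv", results.per_roi,
           delimiter="\t", fmt="%.6g")

means = prs.group_means(results)
print("mean prediction similarity by relationship:")
for rel in ("self_same_scan", "MZ", "DZ", "sibling", "unrelated"):
    if rel in means:
        print(f"  {rel:16s} {means[rel]: .3f}")

tab = results.table
sib = tab[tab["relationship"].isin(prs.SIBLING_CLASSES)]["z_mean"].to_numpy()
unrel = tab[tab["relationship"] == "unrelated"]["z_mean"].to_numpy()
t, p, d = prs.group_contrast(sib, unrel)
print(f"sibling vs unrelated (Welch t on Fisher z): t={t:.2f} p={p:.2e} d={d:.2f}")

oregon = load_cohort(args.data / "oregon_roster.tsv",
                     args.data / "oregon_zygosity.tsv")
counts = prs.comparison_counts(prs.enumerate_comparisons(oregon))
print("youth-style roster enumeration:", counts["ordered"],
      "total", counts["total_ordered"])

(args.out / "fingerprinting.json").write_text(json.dumps(
    {"group_means": means,
     "sibling_vs_unrelated": {"t": t, "p": p, "cohens_d": d},
     "oregon_counts": {**counts["ordered"], "total": counts["total_ordered"]}},
    indent=2))
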