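"""Anatomy-control classifier: can signed per-ROI anatomical differences
(cortical thickness / sulcal depth, optionally adjusted for head size)
classify siblings as well as the connectotype features do?

In the study this is the control establishing that functional familiality
is not explained by anatomy; on the synthetic cohort the anatomical
generator plants its own familial structure, so the point here is that the
machinery (signed differencing, head-size normalization/regression, the
same SVM harness) runs end-to-end and reports per-adjustment accuracies.

Run:  python analysis/04_anatomy_control.py [--runs 50]
"""

import argparse
import json
from pathlib import Path

from connectokin import classifier as clf
from connectokin.cohort_io import load_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--runs", type=int, default=50)
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

cohort = load_cohort(args.data / "roster.tsv", args.data / "zygosity.tsv",
                     anatomy_path=args.data / "anatomy.tsv")
pairs = clf.enumerate_subject_pairs(cohort, n_unrelated=300, seed=args.seed)

report = {}
for measure in ("thickness", "sulcal_depth"):
    for adjust in ("none", "normalize", "regress"):
        fs = clf.anatomical_features(cohort, pairs, measure=measure,
                                     adjust=adjust)
        res = clf.run_experiment(fs, cohort, scheme="family_holdout",
                                 runs=args.runs, null_runs=args.runs,
                                 holdout_families=3, top_p=fs.n_features,
                                 seed=args.seed)
        acc = float(res.accuracy.mean())
        null = float(res.null_accuracy.mean())
        report[f"{measure}/{adjust}"] = {"accuracy": acc, "null": null}
        print(f"{measure:12s} adjust={adjust:9s} accuracy {acc:.3f} "
              f"(null {null:.3f})")

(args.out / "anatomy_control.json").write_text(json.dumps(report, indent=2))
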