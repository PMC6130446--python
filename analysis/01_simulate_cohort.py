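"""Generate the synthetic family-structured cohort used by the later steps.

Writes the full file layout (roster, zygosity pairs, parcellation, per-scan
time courses and FD traces) under results/data/, plus the longitudinal
youth-style roster whose printed bookkeeping the enumeration step checks.

Run:  python analysis/01_simulate_cohort.py [--seed 7]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from connectokin import synthetic as syn
from connectokin.cohort_io import save_cohort, save_parcellation, save_timeseries

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

out = args.out
(out / "timeseries").mkdir(parents=True, exist_ok=True)

# scaled-down HCP-style mix: twins + nontwin siblings + singletons
spec = syn.SyntheticSpec(
    family_templates=(("MZ", 4), ("DZ", 4), ("sib", 16), ("singleton", 8)),
    M=30, frames=240, g2=0.4, c2=0.2, e2=0.4, seed=args.seed)
sim = syn.simulate_cohort(spec, with_anatomy=True)

save_cohort(sim.cohort, out / "roster.tsv", out / "zygosity.tsv")
save_parcellation(sim.parcellation, out / "parcellation.tsv")
sim.cohort.anatomy.to_csv(out / "anatomy.tsv", sep="\t", index=False)
for sid, ts in sim.timeseries.items():
    save_timeseries(ts, out / "timeseries" / f"{sid}.tsv")
    np.savetxt(out / "timeseries" / f"{sid}.fd.txt", sim.fd[sid], fmt="%.6g")

# youth-style longitudinal roster (bookkeeping only; no time courses needed)
oregon = syn.make_oregon_like_pedigree()
save_cohort(oregon, out / "oregon_roster.tsv", out / "oregon_zygosity.tsv")

(out / "spec.json").write_text(json.dumps(
    {"family_templates": spec.family_templates, "M": spec.M,
     "frames": spec.frames, "g2": spec.g2, "c2": spec.c2, "e2": spec.e2,
     "seed": spec.seed}, indent=2))

print(f"wrote {sim.cohort.n_scans} scans ({sim.cohort.n_subjects} subjects, "
      f"{spec.n_families} families) to {out}")
print(f"planted variance fractions: g2={spec.g2} c2={spec.c2} e2={spec.e2}")
print(f"youth-style roster: {oregon.n_subjects} subjects, {oregon.n_scans} scans")
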