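"""End-to-end pipeline runner: simulate/load -> preprocess -> fit/compare ->
classify -> heritability, with deterministic per-stage seeding and a
manifest of every artifact written.

A single global seed spawns per-stage child seeds through
``numpy.random.SeedSequence`` so 1,000-run experiments are reproducible
without storing per-run seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from connectokin import classifier as clf
from connectokin import heritability as her
from connectokin import pairs as prs
from connectokin import synthetic as syn
from connectokin.preprocess import PreprocessConfig, preprocess_scan

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "compare", "classify", "heritability")


@dataclass
class RunConfig:
    """Run configuration; see module docstring for stage order."""

    out_dir: str = "results/run"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic cohort (scaled-down defaults; see SyntheticSpec)
    family_templates: tuple = (("MZ", 5), ("DZ", 5), ("sib", 20), ("singleton", 10))
    M: int = 30
    frames: int = 240
    g2: float = 0.4
    c2: float = 0.2
    # preprocessing
    profile: str = "custom"  # synthetic data needs no censoring by default
    ar_order: int = 1
    do_filter: bool = False
    # connectotype / comparisons
    rank: int | None = None
    cv_folds: int = 4
    n_unrelated_sample: int = 300
    # classifier
    scheme: str = "family_holdout"
    runs: int = 100
    holdout_families: int = 3
    top_p: int = 100
    # heritability
    n_anovas: int = 100
    n_unrelated_match: int = 20

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "family_templates" in raw:
            raw["family_templates"] = tuple(tuple(t) for t in raw["family_templates"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the
    manifest (also written to ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _child_seeds(config.seed, len(STAGES))))
    manifest = {"seed": config.seed, "stage_seeds": seeds, "artifacts": {}}

    def record(path: Path, stage: str):
        manifest["artifacts"][str(path.relative_to(out))] = {
            "stage": stage, "sha256": _sha256(path), "seed": seeds[stage]}

    stage = None
    try:
        stage = "simulate"
        spec = syn.SyntheticSpec(
            family_templates=config.family_templates, M=config.M,
            frames=config.frames, g2=config.g2, c2=config.c2,
            e2=round(1 - config.g2 - config.c2, 12), seed=seeds["simulate"])
        sim = syn.simulate_cohort(spec)
        roster = out / "roster.tsv"
        from connectokin.cohort_io import save_cohort, save_parcellation
        save_cohort(sim.cohort, roster, out / "zygosity.tsv")
        save_parcellation(sim.parcellation, out / "parcellation.tsv")
        for p in (roster, out / "zygosity.tsv", out / "parcellation.tsv"):
            record(p, "simulate")

        stage = "preprocess"
        pcfg = PreprocessConfig(profile=config.profile, ar_order=config.ar_order,
                                do_filter=config.do_filter, do_censor=False)
        residuals = {}
        for sid, ts in sim.timeseries.items():
            residuals[sid], _ = preprocess_scan(ts, cfg=pcfg)

        stage = "compare"
        rng = np.random.default_rng(seeds["compare"])
        pairs = prs.enumerate_comparisons(sim.cohort)
        keep = pairs["relationship"] != "unrelated"
        unrel = pairs[~keep]
        take = unrel.iloc[rng.choice(len(unrel),
                                     size=min(config.n_unrelated_sample, len(unrel)),
                                     replace=False)]
        subset = pd.concat([pairs[keep], take], ignore_index=True)
        results = prs.run_all_comparisons(sim.cohort, residuals, rank=config.rank,
                                          cv_folds=config.cv_folds, pairs=subset)
        comp_path = out / "comparisons.tsv"
        results.table.to_csv(comp_path, sep="\t", index=False)
        record(comp_path, "compare")
        summary = {"group_means": prs.group_means(results)}

        if "classify" in config.stages:
            stage = "classify"
            fs = clf.build_features(results, sim.cohort)
            res = clf.run_experiment(
                fs, sim.cohort, scheme=config.scheme, runs=config.runs,
                holdout_families=config.holdout_families,
                top_p=min(config.top_p, fs.n_features), seed=seeds["classify"])
            summary["classifier"] = res.summary()
            summary["zygosity_strata"] = clf.stratify_by_zygosity(res)

        if "heritability" in config.stages:
            stage = "heritability"
            outcomes = her.pair_outcomes_from_comparisons(results, sim.cohort)
            est = her.estimate_heritability(
                outcomes, "whole_brain",
                n_unrelated_match=min(config.n_unrelated_match,
                                      int((outcomes.genetics == "unrelated").sum())),
                n_anovas=config.n_anovas, seed=seeds["heritability"])
            summary["heritability"] = {
                "h2": est.h2, "c2": est.c2, "h2_ci95": est.h2_ci95,
                "c2_ci95": est.c2_ci95, "n_anovas": est.n_anovas}
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    sum_path = out / "summary.json"
    sum_path.write_text(json.dumps(summary, indent=2, default=float))
    record(sum_path, "heritability" if "heritability" in config.stages else "compare")
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    return manifest
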