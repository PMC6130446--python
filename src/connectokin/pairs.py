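"""Ordered scan-pair comparisons: enumeration, similarity, group contrasts.

Every ordered scan pair (model scan -> target scan), self-inclusive, is a
comparison.  Relationships:

* ``self_same_scan`` — a scan predicting fresh data from its own session;
  the scan's retained frames are split into two disjoint contiguous halves
  (first half fits the model, second half is predicted);
* ``self_other_scan`` — same subject, different session;
* ``MZ`` / ``DZ`` / ``sibling`` — scans of a declared zygosity pair (or of
  two same-family subjects without a declared class, labelled sibling);
* ``unrelated`` — everything else.

Comparisons are directional: (A -> B) and (B -> A) are distinct records, so
an S-scan cohort yields exactly S^2 comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from connectokin.cohort_io import Cohort, ScanTimeSeries
from connectokin.connectotype import (
    Connectotype,
    fisher_z,
    fit_connectotype,
    predict_timecourses,
    similarity,
)

logger = logging.getLogger(__name__)

RELATIONSHIPS = ("self_same_scan", "self_other_scan", "MZ", "DZ", "sibling", "unrelated")

#: Relationship classes that count as a sibling-type (positive) pair.
SIBLING_CLASSES = ("MZ", "DZ", "sibling")


def enumerate_comparisons(cohort: Cohort) -> pd.DataFrame:
    """All S x S ordered, self-inclusive scan pairs with relationship labels.

    Returns a DataFrame with columns model_scan, target_scan, relationship.
    """
    scans = cohort.scans
    subj = dict(zip(scans["scan_id"], scans["subject_id"]))
    fam = dict(zip(cohort.subjects["subject_id"], cohort.subjects["family_id"]))
    zyg = {}
    for _, row in cohort.zygosity_pairs.iterrows():
        zyg[frozenset((row["subject_a"], row["subject_b"]))] = row["zygosity"]
    ids = list(scans["scan_id"])
    rows = []
    for a in ids:
        for b in ids:
            sa, sb = subj[a], subj[b]
            if a == b:
                rel = "self_same_scan"
            elif sa == sb:
                rel = "self_other_scan"
            elif fam[sa] == fam[sb]:
                rel = zyg.get(frozenset((sa, sb)), "sibling")
            else:
                rel = "unrelated"
            rows.append((a, b, rel))
    return pd.DataFrame(rows, columns=["model_scan", "target_scan", "relationship"])


def comparison_counts(comparisons: pd.DataFrame) -> dict:
    """Group sizes, both ordered (as stored) and unordered conventions."""
    ordered = comparisons["relationship"].value_counts().to_dict()
    key = comparisons.apply(
        lambda r: frozenset((r["model_scan"], r["target_scan"])), axis=1
    )
    unordered = (
        comparisons.assign(_k=key).drop_duplicates("_k")["relationship"]
        .value_counts().to_dict()
    )
    return {"ordered": ordered, "unordered": unordered,
            "total_ordered": int(len(comparisons))}


def split_half_self(ts: ScanTimeSeries):
    """Split retained frames into two disjoint contiguous halves.

    The first half (floor(n/2) frames) fits the model; the second half (the
    extra frame on odd counts) evaluates prediction.
    """
    data = ts.retained()
    n = data.shape[0]
    if n < 20:
        raise ValueError(f"need at least 20 retained frames to split, have {n}")
    h = n // 2
    fit = ScanTimeSeries(data=data[:h], tr=ts.tr, scan_id=f"{ts.scan_id}::fit_half")
    ev = ScanTimeSeries(data=data[h:], tr=ts.tr, scan_id=f"{ts.scan_id}::eval_half")
    return fit, ev


@dataclass
class ComparisonResults:
    """All computed pair comparisons for one cohort.

    ``table`` holds one row per comparison (model_scan, target_scan,
    relationship, mean_r, z_mean, n_valid_rois); ``per_roi`` is the aligned
    (n_comparisons, M) matrix of per-ROI prediction-observation correlations
    (NaN where undefined).
    """

    table: pd.DataFrame
    per_roi: np.ndarray


def run_all_comparisons(cohort: Cohort, scans: dict, rank=None, rank_grid=None,
                        cv_folds: int = 4, pairs: pd.DataFrame | None = None,
                        ) -> ComparisonResults:
    """Fit one model per scan and score every enumerated ordered pair.

    Parameters
    ----------
    scans : dict scan_id -> preprocessed (residual) ScanTimeSeries
    rank, rank_grid, cv_folds : forwarded to :func:`fit_connectotype`.
    pairs : optional subset of the enumeration (same columns); by default all
        S^2 ordered pairs are scored.

    Self-same-scan comparisons use a model fit on the first half of the
    scan's frames predicting the disjoint second half; every other
    comparison uses the full-frames model of the model scan predicting the
    target scan's full retained frames.
    """
    if pairs is None:
        pairs = enumerate_comparisons(cohort)
    available = {sid for sid in scans}
    missing = (set(pairs["model_scan"]) | set(pairs["target_scan"])) - available
    if missing:
        logger.warning("skipping %d comparisons with missing scans %s",
                       int(pairs["model_scan"].isin(missing).sum()
                           + pairs["target_scan"].isin(missing).sum()),
                       sorted(missing))
        pairs = pairs[~pairs["model_scan"].isin(missing)
                      & ~pairs["target_scan"].isin(missing)]

    needs_full = set(pairs.loc[pairs["relationship"] != "self_same_scan", "model_scan"])
    needs_split = set(pairs.loc[pairs["relationship"] == "self_same_scan", "model_scan"])

    full_models: dict[str, Connectotype] = {}
    for sid in sorted(needs_full):
        full_models[sid] = fit_connectotype(scans[sid], rank=rank,
                                            rank_grid=rank_grid, cv_folds=cv_folds)
    split_models, eval_halves = {}, {}
    for sid in sorted(needs_split):
        fit_half, eval_half = split_half_self(scans[sid])
        split_models[sid] = fit_connectotype(fit_half, rank=rank,
                                             rank_grid=rank_grid, cv_folds=cv_folds)
        eval_halves[sid] = eval_half

    rows, profiles = [], []
    for _, row in pairs.iterrows():
        a, b, rel = row["model_scan"], row["target_scan"], row["relationship"]
        if rel == "self_same_scan":
            model, target = split_models[a], eval_halves[a]
        else:
            model, target = full_models[a], scans[b]
        pred = predict_timecourses(model, target)
        prof = similarity(pred, target.retained())
        rows.append((a, b, rel, prof.mean_r, fisher_z(prof.mean_r),
                     int(prof.valid_mask.sum())))
        profiles.append(prof.r_per_roi)
    table = pd.DataFrame(rows, columns=["model_scan", "target_scan", "relationship",
                                        "mean_r", "z_mean", "n_valid_rois"])
    return ComparisonResults(table=table, per_roi=np.array(profiles))


def group_means(results: ComparisonResults) -> dict:
    """Mean mean_r per relationship group."""
    return results.table.groupby("relationship")["mean_r"].mean().to_dict()


def group_contrast(z_a: np.ndarray, z_b: np.ndarray):
    """Welch two-sample t test on Fisher-z similarity values, plus Cohen's d.

    Returns (t, p, d)."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if len(z_a) < 2 or len(z_b) < 2:
        raise ValueError("each group needs at least 2 comparisons")
    t, p = stats.ttest_ind(z_a, z_b, equal_var=False)
    na, nb = len(z_a), len(z_b)
    pooled = np.sqrt(((na - 1) * z_a.var(ddof=1) + (nb - 1) * z_b.var(ddof=1))
                     / (na + nb - 2))
    d = (z_a.mean() - z_b.mean()) / pooled if pooled > 0 else 0.0
    if np.isnan(t):  # both groups constant
        t, p = 0.0, 1.0
    return float(t), float(p), float(d)


def interval_association(mean_r: np.ndarray, intervals: np.ndarray):
    """Pearson correlation between cross-session self similarity and the
    inter-session interval.  Returns (R, p)."""
    mean_r = np.asarray(mean_r, dtype=float)
    intervals = np.asarray(intervals, dtype=float)
    if len(mean_r) != len(intervals):
        raise ValueError("length mismatch")
    if len(mean_r) < 3:
        raise ValueError("need at least 3 comparisons with known intervals")
    if np.ptp(intervals) == 0:
        raise ValueError("constant intervals: correlation undefined")
    r, p = stats.pearsonr(mean_r, intervals)
    return float(r), float(p)


def self_other_intervals(cohort: Cohort, results: ComparisonResults) -> pd.DataFrame:
    """Attach inter-session intervals to self_other_scan comparisons.

    Sessions must be numeric (ordinals or years); the interval is the
    absolute session difference.
    """
    sess = dict(zip(cohort.scans["scan_id"],
                    pd.to_numeric(cohort.scans["session"], errors="coerce")))
    sub = results.table[results.table["relationship"] == "self_other_scan"].copy()
    sub["interval"] = [abs(sess[a] - sess[b])
                       for a, b in zip(sub["model_scan"], sub["target_scan"])]
    return sub
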