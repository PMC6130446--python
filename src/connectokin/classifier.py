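"""Sibling-versus-unrelated classification of scan-pair comparisons.

Feature vectors are the per-ROI prediction-observation correlations of a
comparison (or signed per-ROI anatomical differences of a subject pair).
On each run, features are ranked on the training partition only by the
two-sample Kolmogorov-Smirnov statistic, the top-p kept, a linear SVM tuned
by leave-one-out cross-validation on the training partition, and accuracy
measured on held-out rows.  Permutation nulls rerun the identical machinery
with training labels shuffled.

Two partition schemes:

* ``scanpair_holdout`` — a fixed number of sibling scan-pairs (both
  directions together) reserved for prediction each run; mirrors a
  longitudinal design where the same family may appear in training at
  another timepoint.
* ``family_holdout`` — whole families reserved for prediction; families
  containing twins never enter training, so twin detection is generalization
  from nontwin-sibling training signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from connectokin.cohort_io import Cohort, ParcellationTable
from connectokin.pairs import SIBLING_CLASSES, ComparisonResults

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-3, 4))

#: libsvm iteration cap: on permuted-label (null) training sets large C
#: values otherwise iterate for minutes; an under-converged large-C fit is
#: simply not selected by LOOCV.
SVC_MAX_ITER = 2000


def _svc(C: float) -> SVC:
    import warnings as _w
    from sklearn.exceptions import ConvergenceWarning
    _w.filterwarnings("ignore", category=ConvergenceWarning)
    return SVC(kernel="linear", C=C, max_iter=SVC_MAX_ITER)


@dataclass
class FeatureSet:
    """Per-comparison feature rows with labels and family bookkeeping.

    ``y`` is 1 for the sibling class (MZ/DZ/nontwin sibling) and 0 for
    unrelated.  ``meta`` carries, per row: model_scan, target_scan,
    relationship, zygosity (sibling class or ''), family_a, family_b, and
    pair_key (order-free subject-pair identifier grouping both directions).
    """

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self):
        assert self.X.shape[0] == len(self.y) == len(self.meta)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(self.X[idx], self.y[idx],
                          self.meta.iloc[idx].reset_index(drop=True))


def build_features(results: ComparisonResults, cohort: Cohort,
                   max_invalid_frac: float = 0.2) -> FeatureSet:
    """Feature rows from computed comparisons.

    Self comparisons are excluded; rows with more than ``max_invalid_frac``
    undefined ROI correlations are dropped (remaining undefined entries are
    imputed 0).
    """
    tab = results.table
    keep = tab["relationship"].isin(SIBLING_CLASSES + ("unrelated",)).to_numpy()
    if not (tab.loc[keep, "relationship"].isin(SIBLING_CLASSES)).any():
        raise ValueError("no positive class: no sibling-type comparisons present")
    X = results.per_roi[keep].copy()
    tab = tab.loc[keep].reset_index(drop=True)
    invalid = np.isnan(X)
    frac = invalid.mean(axis=1)
    ok = frac <= max_invalid_frac
    if (~ok).any():
        logger.warning("dropping %d comparisons with >%d%% invalid ROIs",
                       int((~ok).sum()), int(100 * max_invalid_frac))
    X, tab = X[ok], tab.loc[ok].reset_index(drop=True)
    X = np.nan_to_num(X, nan=0.0)

    subj = dict(zip(cohort.scans["scan_id"], cohort.scans["subject_id"]))
    fam = dict(zip(cohort.subjects["subject_id"], cohort.subjects["family_id"]))
    sa = tab["model_scan"].map(subj)
    sb = tab["target_scan"].map(subj)
    meta = pd.DataFrame({
        "model_scan": tab["model_scan"],
        "target_scan": tab["target_scan"],
        "relationship": tab["relationship"],
        "zygosity": tab["relationship"].where(
            tab["relationship"].isin(SIBLING_CLASSES), ""),
        "family_a": sa.map(fam),
        "family_b": sb.map(fam),
        "pair_key": [" | ".join(sorted((a, b))) for a, b in zip(sa, sb)],
    })
    y = tab["relationship"].isin(SIBLING_CLASSES).to_numpy().astype(int)
    return FeatureSet(X=X, y=y, meta=meta)


# ---------------------------------------------------------------------------
# anatomy-derived features


def enumerate_subject_pairs(cohort: Cohort, n_unrelated: int | None = None,
                            seed=None) -> pd.DataFrame:
    """Sibling-class subject pairs plus (optionally sampled) unrelated pairs."""
    rng = np.random.default_rng(seed)
    fam = dict(zip(cohort.subjects["subject_id"], cohort.subjects["family_id"]))
    zyg = {frozenset((r["subject_a"], r["subject_b"])): r["zygosity"]
           for _, r in cohort.zygosity_pairs.iterrows()}
    subjects = list(cohort.subjects["subject_id"])
    rows = []
    for i, a in enumerate(subjects):
        for b in subjects[i + 1:]:
            if fam[a] == fam[b]:
                rows.append((a, b, zyg.get(frozenset((a, b)), "sibling")))
            else:
                rows.append((a, b, "unrelated"))
    df = pd.DataFrame(rows, columns=["subject_a", "subject_b", "relationship"])
    if n_unrelated is not None:
        unrel = df[df["relationship"] == "unrelated"]
        take = unrel.iloc[rng.choice(len(unrel), size=min(n_unrelated, len(unrel)),
                                     replace=False)]
        df = pd.concat([df[df["relationship"] != "unrelated"], take],
                       ignore_index=True)
    return df


def anatomical_features(cohort: Cohort, subject_pairs: pd.DataFrame,
                        measure: str = "thickness",
                        adjust: str = "none") -> FeatureSet:
    """Signed per-ROI anatomical differences as pair features.

    ``adjust='normalize'`` divides each subject's measures by their head
    size; ``adjust='regress'`` removes head size from each ROI's measure by
    least squares across subjects before differencing.
    """
    if cohort.anatomy is None:
        raise ValueError("cohort has no anatomy table")
    anat = cohort.anatomy
    wide = anat.pivot(index="subject_id", columns="roi_id", values=measure)
    head = anat.groupby("subject_id")["head_size"].first()
    if adjust == "normalize":
        wide = wide.div(head.reindex(wide.index), axis=0)
    elif adjust == "regress":
        h = head.reindex(wide.index).to_numpy()
        Xh = np.column_stack([np.ones_like(h), h])
        beta, *_ = np.linalg.lstsq(Xh, wide.to_numpy(), rcond=None)
        wide = pd.DataFrame(wide.to_numpy() - Xh @ beta,
                            index=wide.index, columns=wide.columns)
    elif adjust != "none":
        raise ValueError(f"unknown adjust mode {adjust!r}")

    fam = dict(zip(cohort.subjects["subject_id"], cohort.subjects["family_id"]))
    rows, feats = [], []
    for _, r in subject_pairs.iterrows():
        a, b = r["subject_a"], r["subject_b"]
        if a not in wide.index or b not in wide.index:
            logger.warning("dropping pair (%s, %s): missing anatomy", a, b)
            continue
        va, vb = wide.loc[a].to_numpy(), wide.loc[b].to_numpy()
        if np.isnan(va).any() or np.isnan(vb).any():
            logger.warning("dropping pair (%s, %s): missing ROI measure", a, b)
            continue
        feats.append(va - vb)
        rel = r["relationship"]
        rows.append((a, b, rel, rel if rel in SIBLING_CLASSES else "",
                     fam[a], fam[b], " | ".join(sorted((a, b)))))
    meta = pd.DataFrame(rows, columns=["model_scan", "target_scan", "relationship",
                                       "zygosity", "family_a", "family_b",
                                       "pair_key"])
    y = meta["relationship"].isin(SIBLING_CLASSES).to_numpy().astype(int)
    return FeatureSet(X=np.array(feats), y=y, meta=meta)


# ---------------------------------------------------------------------------
# KS feature ranking


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov D = sup |F_a - F_b| (empirical CDFs)."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pooled = np.concatenate([a, b])
    ca = np.searchsorted(a, pooled, side="right") / len(a)
    cb = np.searchsorted(b, pooled, side="right") / len(b)
    return float(np.abs(ca - cb).max())


def rank_features_ks(X: np.ndarray, y: np.ndarray):
    """Rank feature columns by descending between-class KS statistic.

    Returns (order, D) where ``order`` are column indices best-first.
    Constant features score D = 0 and sort last (stable sort keeps their
    original relative order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 rows per class to rank features")
    D = np.array([ks_statistic(X[y, j], X[~y, j]) for j in range(X.shape[1])])
    order = np.argsort(-D, kind="stable")
    return order, D


# ---------------------------------------------------------------------------
# SVM training


@dataclass
class TunedSVM:
    scaler: StandardScaler
    svm: SVC
    C: float
    loocv_accuracy: float
    feature_idx: np.ndarray  # columns (of the full feature space) used

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.scaler.transform(X[:, self.feature_idx]))


def _loocv_accuracy(Xs: np.ndarray, y: np.ndarray, C: float) -> float:
    """Exact leave-one-out accuracy.

    Removing a non-support vector leaves the SVM solution unchanged, and a
    non-support vector lies strictly outside the margin on its own side, so
    it is leave-one-out correct; only support vectors need a refit."""
    n = len(y)
    full = _svc(C).fit(Xs, y)
    sv = np.zeros(n, dtype=bool)
    sv[full.support_] = True
    correct = int((~sv).sum())
    idx = np.arange(n)
    for i in np.flatnonzero(sv):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            continue  # degenerate split counts as an error
        clf = _svc(C).fit(Xs[tr], y[tr])
        correct += int(clf.predict(Xs[i:i + 1])[0] == y[i])
    return correct / n


def train_tuned_svm(X: np.ndarray, y: np.ndarray, top_p: int | None = None,
                    feature_idx: np.ndarray | None = None,
                    c_grid=DEFAULT_C_GRID) -> TunedSVM:
    """Linear SVM with C chosen by leave-one-out CV on the training rows.

    Feature ranking (KS) and standardization are learned on the training
    rows only.  LOOCV ties break toward the smaller C (stronger
    regularization).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    if feature_idx is None:
        order, _ = rank_features_ks(X, y)
        if top_p is None:
            top_p = X.shape[1]
        if top_p > X.shape[1]:
            logger.warning("top_p %d clipped to %d features", top_p, X.shape[1])
            top_p = X.shape[1]
        feature_idx = np.sort(order[:top_p])
    scaler = StandardScaler().fit(X[:, feature_idx])
    Xs = scaler.transform(X[:, feature_idx])
    best_C, best_acc = None, -1.0
    for C in sorted(c_grid):
        acc = _loocv_accuracy(Xs, y, C)
        if acc > best_acc:  # strict: ties keep the smaller C
            best_C, best_acc = C, acc
    svm = _svc(best_C).fit(Xs, y)
    return TunedSVM(scaler=scaler, svm=svm, C=best_C,
                    loocv_accuracy=best_acc, feature_idx=feature_idx)


# ---------------------------------------------------------------------------
# experiments


@dataclass
class ExperimentResult:
    """Per-run out-of-sample metrics, matched permutation null, and
    selected-feature tallies."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    null_accuracy: np.ndarray
    stratum_accuracy: pd.DataFrame  # columns MZ, DZ, sibling (NaN if absent)
    selection_counts: np.ndarray  # per-ROI times among top-p
    runs: int
    seed: object

    def summary(self) -> dict:
        def bands(x):
            x = x[~np.isnan(x)]
            if len(x) == 0:
                return None
            return {"mean": float(np.mean(x)),
                    "p2.5": float(np.percentile(x, 2.5)),
                    "p25": float(np.percentile(x, 25)),
                    "p75": float(np.percentile(x, 75)),
                    "p97.5": float(np.percentile(x, 97.5))}
        out = {"accuracy": bands(self.accuracy),
               "sensitivity": bands(self.sensitivity),
               "specificity": bands(self.specificity),
               "null_accuracy": bands(self.null_accuracy),
               "runs": self.runs}
        for z in ("MZ", "DZ", "sibling"):
            col = self.stratum_accuracy[z].to_numpy()
            out[f"accuracy_{z}"] = bands(col)
        return out


def _partition_scanpair(fs: FeatureSet, holdout_pairs: int, rng):
    """Reserve `holdout_pairs` sibling scan-pairs (both directions together)
    for prediction; remaining sibling rows train.  The same siblings at
    other scan timepoints may remain in training (longitudinal design)."""
    pos = np.flatnonzero(fs.y == 1)
    keys = np.array([" | ".join(sorted((a, b))) for a, b in
                     zip(fs.meta["model_scan"], fs.meta["target_scan"])])
    pos_keys = np.unique(keys[pos])
    if len(pos_keys) <= holdout_pairs:
        raise ValueError("not enough sibling scan-pairs to hold out")
    held = set(rng.choice(pos_keys, size=holdout_pairs, replace=False))
    test_pos = pos[np.isin(keys[pos], list(held))]
    train_pos = pos[~np.isin(keys[pos], list(held))]
    return train_pos, test_pos


def _partition_family(fs: FeatureSet, cohort: Cohort, holdout_families: int, rng):
    """Reserve whole sibling families for prediction; train only on families
    without twins."""
    pos = np.flatnonzero(fs.y == 1)
    fam_a = fs.meta["family_a"].to_numpy()
    pos_fams = np.unique(fam_a[pos])  # sibling rows are within-family
    if len(pos_fams) <= holdout_families:
        raise ValueError(
            f"only {len(pos_fams)} sibling families; cannot hold out {holdout_families}")
    held = set(rng.choice(pos_fams, size=holdout_families, replace=False))
    twin_fams = cohort.families_with_twins()
    test_pos = pos[np.isin(fam_a[pos], list(held))]
    train_ok = ~np.isin(fam_a[pos], list(held)) & ~np.isin(fam_a[pos], list(twin_fams))
    train_pos = pos[train_ok]
    return train_pos, test_pos, held, twin_fams


def _sample_matched_unrelated(fs: FeatureSet, n_train: int, n_test: int,
                              banned_train_fams: set, rng):
    """Class-balanced unrelated rows: disjoint training/testing samples,
    training rows avoiding banned families."""
    neg = np.flatnonzero(fs.y == 0)
    fa = fs.meta["family_a"].to_numpy()
    fb = fs.meta["family_b"].to_numpy()
    banned = np.isin(fa, list(banned_train_fams)) | np.isin(fb, list(banned_train_fams))
    train_pool = neg[~banned[neg]]
    if len(train_pool) < n_train:
        raise ValueError("unrelated pool too small for training match")
    train_neg = rng.choice(train_pool, size=n_train, replace=False)
    test_pool = np.setdiff1d(neg, train_neg)
    if len(test_pool) < n_test:
        raise ValueError("unrelated pool too small for testing match")
    test_neg = rng.choice(test_pool, size=n_test, replace=False)
    return train_neg, test_neg


def _one_run(fs: FeatureSet, train_idx, test_idx, top_p, c_grid, rng,
             permute_train_labels=False):
    assert len(np.intersect1d(train_idx, test_idx)) == 0, "train/test leakage"
    Xtr, ytr = fs.X[train_idx], fs.y[train_idx]
    if permute_train_labels:
        ytr = rng.permutation(ytr)
    model = train_tuned_svm(Xtr, ytr, top_p=top_p, c_grid=c_grid)
    pred = model.predict(fs.X[test_idx])
    yte = fs.y[test_idx]
    acc = float(np.mean(pred == yte))
    sens = float(np.mean(pred[yte == 1] == 1)) if (yte == 1).any() else np.nan
    spec = float(np.mean(pred[yte == 0] == 0)) if (yte == 0).any() else np.nan
    strata = {}
    zyg = fs.meta["zygosity"].to_numpy()[test_idx]
    for z in ("MZ", "DZ", "sibling"):
        m = (yte == 1) & (zyg == z)
        strata[z] = float(np.mean(pred[m] == 1)) if m.any() else np.nan
    return acc, sens, spec, strata, model.feature_idx


def run_experiment(fs: FeatureSet, cohort: Cohort, scheme: str = "family_holdout",
                   runs: int = 1000, holdout_families: int = 3, top_p: int = 100,
                   c_grid=DEFAULT_C_GRID, seed=None,
                   null_runs: int | None = None) -> ExperimentResult:
    """Repeated family-aware holdout SVM experiment with a permutation null.

    Each run draws a fresh holdout, a fresh class-balanced unrelated sample,
    re-ranks features on training rows only, tunes C by LOOCV, and scores
    the held-out rows.  The null repeats identical machinery with training
    labels shuffled.
    """
    if scheme not in ("family_holdout", "scanpair_holdout"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    if null_runs is None:
        null_runs = runs
    acc = np.empty(runs)
    sens = np.empty(runs)
    spec = np.empty(runs)
    strat_rows = []
    sel = np.zeros(fs.n_features)
    nulls = np.empty(null_runs)

    def draw_partition():
        if scheme == "family_holdout":
            train_pos, test_pos, held, twin_fams = _partition_family(
                fs, cohort, holdout_families, rng)
            banned = held | twin_fams
        else:
            train_pos, test_pos = _partition_scanpair(fs, holdout_families, rng)
            banned = set()
        train_neg, test_neg = _sample_matched_unrelated(
            fs, len(train_pos), max(len(test_pos), 1), banned, rng)
        train_idx = np.concatenate([train_pos, train_neg])
        test_idx = np.concatenate([test_pos, test_neg])
        if scheme == "family_holdout":
            # leakage guard: held-out families never in training
            tr_f = set(fs.meta["family_a"].to_numpy()[train_idx]) \
                | set(fs.meta["family_b"].to_numpy()[train_idx])
            te_pos_f = set(fs.meta["family_a"].to_numpy()[test_pos])
            assert not (tr_f & te_pos_f), "holdout family leaked into training"
        return train_idx, test_idx

    for r in range(runs):
        train_idx, test_idx = draw_partition()
        a, s, p, strata, fidx = _one_run(fs, train_idx, test_idx, top_p, c_grid, rng)
        acc[r], sens[r], spec[r] = a, s, p
        strat_rows.append(strata)
        sel[fidx] += 1
    for r in range(null_runs):
        train_idx, test_idx = draw_partition()
        a, *_ = _one_run(fs, train_idx, test_idx, top_p, c_grid, rng,
                         permute_train_labels=True)
        nulls[r] = a
    return ExperimentResult(
        accuracy=acc, sensitivity=sens, specificity=spec, null_accuracy=nulls,
        stratum_accuracy=pd.DataFrame(strat_rows, columns=["MZ", "DZ", "sibling"]),
        selection_counts=sel, runs=runs, seed=seed)


def stratify_by_zygosity(result: ExperimentResult) -> dict:
    """Summarize held-out positive-class accuracy by zygosity, with a
    rank-sum test and Cohen's d contrasting MZ vs DZ run-wise accuracies."""
    out = {}
    for z in ("MZ", "DZ", "sibling"):
        col = result.stratum_accuracy[z].to_numpy()
        col = col[~np.isnan(col)]
        out[z] = float(np.mean(col)) if len(col) else None
    mz = result.stratum_accuracy["MZ"].dropna().to_numpy()
    dz = result.stratum_accuracy["DZ"].dropna().to_numpy()
    if len(mz) >= 2 and len(dz) >= 2:
        stat, p = stats.ranksums(mz, dz)
        pooled = np.sqrt((mz.var(ddof=1) + dz.var(ddof=1)) / 2)
        d = (mz.mean() - dz.mean()) / pooled if pooled > 0 else 0.0
        out["mz_vs_dz"] = {"ranksum": float(stat), "p": float(p),
                           "cohens_d": float(d)}
    else:
        out["mz_vs_dz"] = None
    return out


def cross_dataset_experiment(train_fs: FeatureSet, test_fs: FeatureSet,
                             runs: int = 1000, top_p: int = 100,
                             c_grid=DEFAULT_C_GRID, seed=None,
                             null_runs: int | None = None) -> ExperimentResult:
    """Train on one dataset, predict siblings in the other.

    Per run: all training sibling rows plus an equal resampled unrelated
    sample train the classifier (ranking, scaling, LOOCV tuning from the
    training dataset only); all test-dataset sibling rows plus an equal
    resampled unrelated sample are scored.
    """
    if train_fs.n_features != test_fs.n_features:
        raise ValueError(
            f"feature spaces differ ({train_fs.n_features} vs {test_fs.n_features}); "
            "datasets must share a parcellation")
    rng = np.random.default_rng(seed)
    if null_runs is None:
        null_runs = runs
    tr_pos = np.flatnonzero(train_fs.y == 1)
    tr_neg = np.flatnonzero(train_fs.y == 0)
    te_pos = np.flatnonzero(test_fs.y == 1)
    te_neg = np.flatnonzero(test_fs.y == 0)

    def one(permute):
        tneg = rng.choice(tr_neg, size=len(tr_pos), replace=False)
        train_idx = np.concatenate([tr_pos, tneg])
        ytr = train_fs.y[train_idx]
        if permute:
            ytr = rng.permutation(ytr)
        model = train_tuned_svm(train_fs.X[train_idx], ytr, top_p=top_p,
                                c_grid=c_grid)
        eneg = rng.choice(te_neg, size=min(len(te_pos), len(te_neg)), replace=False)
        test_idx = np.concatenate([te_pos, eneg])
        pred = model.predict(test_fs.X[test_idx])
        yte = test_fs.y[test_idx]
        acc = float(np.mean(pred == yte))
        sens = float(np.mean(pred[yte == 1] == 1))
        spec = float(np.mean(pred[yte == 0] == 0)) if (yte == 0).any() else np.nan
        strata = {}
        zyg = test_fs.meta["zygosity"].to_numpy()[test_idx]
        for z in ("MZ", "DZ", "sibling"):
            m = (yte == 1) & (zyg == z)
            strata[z] = float(np.mean(pred[m] == 1)) if m.any() else np.nan
        return acc, sens, spec, strata, model.feature_idx

    acc = np.empty(runs)
    sens = np.empty(runs)
    spec = np.empty(runs)
    strat_rows = []
    sel = np.zeros(train_fs.n_features)
    for r in range(runs):
        acc[r], sens[r], spec[r], strata, fidx = one(False)
        strat_rows.append(strata)
        sel[fidx] += 1
    nulls = np.array([one(True)[0] for _ in range(null_runs)])
    return ExperimentResult(
        accuracy=acc, sensitivity=sens, specificity=spec, null_accuracy=nulls,
        stratum_accuracy=pd.DataFrame(strat_rows, columns=["MZ", "DZ", "sibling"]),
        selection_counts=sel, runs=runs, seed=seed)


def per_network_experiment(fs: FeatureSet, cohort: Cohort,
                           parcellation: ParcellationTable, runs: int = 100,
                           scheme: str = "family_holdout",
                           holdout_families: int = 3, c_grid=DEFAULT_C_GRID,
                           seed=None) -> dict:
    """One experiment per functional network using only that network's ROIs
    (all of them; no KS pre-selection within a network)."""
    rng = np.random.default_rng(seed)
    out = {}
    labels = list(parcellation.networks) + ["unassigned"]
    for net in labels:
        cols = parcellation.network_members(net)
        if len(cols) < 2:
            logger.warning("skipping network %s with %d ROIs", net, len(cols))
            continue
        sub = FeatureSet(fs.X[:, cols], fs.y, fs.meta)
        out[net] = run_experiment(
            sub, cohort, scheme=scheme, runs=runs,
            holdout_families=holdout_families, top_p=len(cols),
            c_grid=c_grid, seed=int(rng.integers(2 ** 31)))
    return out


def roi_size_confound(selection_counts: np.ndarray,
                      parcellation: ParcellationTable, top_n: int = 100):
    """KS test comparing sizes (n_vertices) of the `top_n` most-selected
    ROIs versus the rest; returns (k, p)."""
    sizes = parcellation.table["n_vertices"].to_numpy()
    if not 0 < top_n < len(sizes):
        raise ValueError("top_n must leave both a selected and an excluded set")
    order = np.argsort(-selection_counts, kind="stable")
    chosen = np.zeros(len(sizes), dtype=bool)
    chosen[order[:top_n]] = True
    k, p = stats.ks_2samp(sizes[chosen], sizes[~chosen])
    return float(k), float(p)
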