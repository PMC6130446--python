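"""Heritability and shared environment as ANOVA sum-of-squares fractions.

The outcome for a subject pair is its vector of per-ROI prediction
correlations (averaged over the two comparison directions so each pair
contributes once).  Pairs carry two between-pair factors:

* shared environment — ``related`` (MZ/DZ/nontwin sibling) vs ``unrelated``;
* shared genetics — ``MZ`` vs ``DZ_or_sib`` vs ``unrelated``.

Outcomes are rank-inverse-normal transformed per ROI, then enter a
three-way repeated-measures ANOVA (environment x genetics x ROI, ROI the
within-pair repeated measure).  Heritability h2 is the genetics
sum-of-squares over the total, shared environment c2 the environment SS
over the total.

The two pair-level factors are partially aliased by construction: the
environment factor is a coarsening of the genetics factor.  Sequential
(Type-I) SS with ROI entered first, environment second, genetics third is
the only ordering under which both main effects are estimable; genetics
then captures exactly the MZ vs DZ/sibling contrast beyond relatedness,
and with no MZ pairs its SS is exactly zero (flagged "aliased").
Interactions are pooled into the residual.

Because every pair is observed at every ROI, the design is balanced: ROI
effects are exactly orthogonal to the pair-level factors, so the sequential
SS decomposition is computed in closed form from ROI means and pair means
(verified against a dense design-matrix ANOVA in the test suite).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENETICS_LEVELS = ("MZ", "DZ_or_sib", "unrelated")

#: map from comparison relationship to the genetics factor level
RELATION_TO_GENETICS = {"MZ": "MZ", "DZ": "DZ_or_sib", "sibling": "DZ_or_sib",
                        "unrelated": "unrelated"}


@dataclass
class PairOutcomes:
    """Per-pair per-ROI outcomes plus factor levels.

    Y has shape (n_pairs, n_rois); ``genetics`` holds one of
    ``GENETICS_LEVELS`` per pair (the environment factor is derived:
    related unless genetics == 'unrelated').
    """

    Y: np.ndarray
    genetics: np.ndarray  # dtype object/str, length n_pairs
    roi_ids: np.ndarray = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.genetics = np.asarray(self.genetics, dtype=object)
        if self.Y.shape[0] != len(self.genetics):
            raise ValueError("Y rows must match genetics labels")
        bad = set(self.genetics) - set(GENETICS_LEVELS)
        if bad:
            raise ValueError(f"unknown genetics levels {sorted(bad)}")
        if self.roi_ids is None:
            self.roi_ids = np.arange(1, self.Y.shape[1] + 1)

    @property
    def environment(self) -> np.ndarray:
        return np.where(self.genetics == "unrelated", "unrelated", "related")

    def subset_pairs(self, idx) -> "PairOutcomes":
        idx = np.asarray(idx)
        return PairOutcomes(self.Y[idx], self.genetics[idx], self.roi_ids)


def pair_outcomes_from_comparisons(results, cohort) -> PairOutcomes:
    """Average the two directions of each sibling-class / unrelated
    comparison into one outcome row per subject pair."""
    tab = results.table
    subj = dict(zip(cohort.scans["scan_id"], cohort.scans["subject_id"]))
    rows = {}
    for i, row in tab.iterrows():
        rel = row["relationship"]
        if rel not in RELATION_TO_GENETICS:
            continue
        key = frozenset((subj[row["model_scan"]], subj[row["target_scan"]]))
        rows.setdefault((key, RELATION_TO_GENETICS[rel]), []).append(i)
    Y, gen = [], []
    for (key, g), idx in rows.items():
        Y.append(np.nanmean(results.per_roi[idx], axis=0))
        gen.append(g)
    Y = np.array(Y)
    if np.isnan(Y).any():
        Y = np.nan_to_num(Y, nan=0.0)
    return PairOutcomes(Y=Y, genetics=np.array(gen, dtype=object))


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: values are replaced by normal
    quantiles of (rank - 0.5)/n, ties receiving the average rank."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        warnings.warn("all-equal input to rank_inverse_normal; returning zeros")
        return np.zeros_like(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


@dataclass
class AnovaSS:
    """Sequential sum-of-squares table (ROI -> environment -> genetics)."""

    ss_roi: float
    ss_environment: float
    ss_genetics: float
    ss_residual: float
    ss_total: float
    df: dict
    aliased: bool  # genetics adds nothing beyond environment

    @property
    def h2(self) -> float:
        return self.ss_genetics / self.ss_total if self.ss_total > 0 else 0.0

    @property
    def c2(self) -> float:
        return self.ss_environment / self.ss_total if self.ss_total > 0 else 0.0

    def f_test(self, term: str):
        """F test of a factor against the residual; returns (F, p)."""
        ss = {"environment": self.ss_environment, "genetics": self.ss_genetics,
              "roi": self.ss_roi}[term]
        df1 = self.df[term]
        df2 = self.df["residual"]
        if df1 == 0 or df2 <= 0 or self.ss_residual <= 0:
            return np.nan, np.nan
        F = (ss / df1) / (self.ss_residual / df2)
        return float(F), float(stats.f.sf(F, df1, df2))


def _group_fit(z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fitted values of a one-way group-means model."""
    out = np.empty_like(z)
    for g in np.unique(labels):
        m = labels == g
        out[m] = z[m].mean()
    return out


def rm_anova_ss(outcomes: PairOutcomes, roi_subset=None) -> AnovaSS:
    """Sequential SS for the repeated-measures design.

    ``roi_subset``: 0-based ROI column indices (default all).  Both
    environment levels must be present.  With no MZ (or no DZ/sib) pairs
    among the related pairs, genetics is fully aliased with environment and
    its SS is reported as exactly 0.
    """
    Y = outcomes.Y if roi_subset is None else outcomes.Y[:, np.asarray(roi_subset)]
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] == 0:
        raise ValueError("roi_subset is empty")
    env = outcomes.environment
    gen = outcomes.genetics
    if len(set(env)) < 2:
        raise ValueError("both environment levels (related/unrelated) required")
    P, R = Y.shape
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    # balanced design: ROI effects orthogonal to pair-level factors
    roi_means = Y.mean(axis=0)
    ss_roi = float(P * ((roi_means - grand) ** 2).sum())

    z = Y.mean(axis=1)  # pair means; pair-level SS scale back by R
    fit_env = _group_fit(z, env)
    ss_env = float(R * ((fit_env - grand) ** 2).sum())

    related_levels = set(gen[env == "related"])
    aliased = len(related_levels) < 2
    if aliased:
        ss_gen = 0.0
        df_gen = 0
        logger.warning("genetics factor aliased with environment "
                       "(related levels present: %s)", sorted(related_levels))
    else:
        fit_gen = _group_fit(z, gen)
        ss_gen = float(R * ((fit_gen - fit_env) ** 2).sum())
        df_gen = len(set(gen)) - len(set(env))
    ss_resid = ss_total - ss_roi - ss_env - ss_gen
    df = {"roi": R - 1, "environment": len(set(env)) - 1, "genetics": df_gen}
    df["residual"] = P * R - 1 - df["roi"] - df["environment"] - df["genetics"]
    return AnovaSS(ss_roi=ss_roi, ss_environment=ss_env, ss_genetics=ss_gen,
                   ss_residual=ss_resid, ss_total=ss_total, df=df,
                   aliased=aliased)


@dataclass
class HeritabilityEstimate:
    """Resampling summary of h2/c2 SS fractions at one level."""

    level: str
    h2: float
    c2: float
    h2_ci95: tuple
    c2_ci95: tuple
    n_anovas: int
    p_genetics: float
    p_environment: float
    unreliable: bool = False


def estimate_heritability(outcomes: PairOutcomes, level: str = "whole_brain",
                          roi_subset=None, n_unrelated_match: int = 58,
                          n_anovas: int = 1000, seed=None,
                          transform: bool = True) -> HeritabilityEstimate:
    """h2/c2 with percentile CIs over repeated ANOVAs, each on a fresh random
    matched subset of unrelated pairs.

    ``level`` is a label ("whole_brain", "network:<name>", "roi:<id>");
    ``roi_subset`` selects the outcome columns entering the ANOVA (all by
    default).  Outcomes are rank-inverse-normal transformed per ROI within
    each ANOVA's pair subset.  p-values are medians of the per-ANOVA F
    tests; multiple-comparison correction across ROI-level estimates is the
    caller's responsibility (see :func:`correct_pvalues`).
    """
    rng = np.random.default_rng(seed)
    gen = outcomes.genetics
    related_idx = np.flatnonzero(gen != "unrelated")
    unrel_idx = np.flatnonzero(gen == "unrelated")
    if len(unrel_idx) < n_unrelated_match:
        raise ValueError(
            f"unrelated pool ({len(unrel_idx)}) smaller than match size "
            f"{n_unrelated_match}")
    unreliable = any((gen == g).sum() < 2 for g in ("MZ", "DZ_or_sib"))
    if unreliable:
        logger.warning("fewer than 2 pairs in a genetics level; "
                       "estimate flagged unreliable")
    h2s = np.empty(n_anovas)
    c2s = np.empty(n_anovas)
    pg = np.empty(n_anovas)
    pe = np.empty(n_anovas)
    for a in range(n_anovas):
        sub = rng.choice(unrel_idx, size=n_unrelated_match, replace=False)
        idx = np.concatenate([related_idx, sub])
        o = outcomes.subset_pairs(idx)
        if roi_subset is not None:
            cols = np.atleast_1d(np.asarray(roi_subset))
            o = PairOutcomes(Y=o.Y[:, cols], genetics=o.genetics,
                             roi_ids=o.roi_ids[cols])
        if transform:
            Y = np.column_stack([rank_inverse_normal(o.Y[:, j])
                                 for j in range(o.Y.shape[1])])
            o = PairOutcomes(Y=Y, genetics=o.genetics, roi_ids=o.roi_ids)
        table = rm_anova_ss(o)
        h2s[a], c2s[a] = table.h2, table.c2
        _, pg[a] = table.f_test("genetics")
        _, pe[a] = table.f_test("environment")
    return HeritabilityEstimate(
        level=level,
        h2=float(np.mean(h2s)), c2=float(np.mean(c2s)),
        h2_ci95=(float(np.percentile(h2s, 2.5)), float(np.percentile(h2s, 97.5))),
        c2_ci95=(float(np.percentile(c2s, 2.5)), float(np.percentile(c2s, 97.5))),
        n_anovas=n_anovas,
        p_genetics=float(np.nanmedian(pg)), p_environment=float(np.nanmedian(pe)),
        unreliable=unreliable)


def estimate_all_levels(outcomes: PairOutcomes, parcellation=None,
                        n_unrelated_match: int = 58, n_anovas: int = 1000,
                        seed=None, correction: str = "bonferroni") -> pd.DataFrame:
    """Whole-brain, per-network, and per-ROI estimates as one table.

    ROI-level p-values are corrected for multiple comparisons across all
    ROIs (Bonferroni by default, Benjamini-Hochberg via
    ``correction='fdr_bh'``).
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(est: HeritabilityEstimate, kind: str):
        rows.append({"level": est.level, "kind": kind, "h2": est.h2, "c2": est.c2,
                     "h2_lo": est.h2_ci95[0], "h2_hi": est.h2_ci95[1],
                     "c2_lo": est.c2_ci95[0], "c2_hi": est.c2_ci95[1],
                     "p_genetics": est.p_genetics,
                     "p_environment": est.p_environment,
                     "unreliable": est.unreliable})

    add(estimate_heritability(outcomes, "whole_brain", None, n_unrelated_match,
                              n_anovas, int(rng.integers(2 ** 31))), "whole_brain")
    if parcellation is not None:
        for net in parcellation.networks:
            cols = parcellation.network_members(net)
            if len(cols) == 0:
                continue
            add(estimate_heritability(outcomes, f"network:{net}", cols,
                                      n_unrelated_match, n_anovas,
                                      int(rng.integers(2 ** 31))), "network")
    for j, rid in enumerate(outcomes.roi_ids):
        add(estimate_heritability(outcomes, f"roi:{rid}", [j], n_unrelated_match,
                                  n_anovas, int(rng.integers(2 ** 31))), "roi")
    df = pd.DataFrame(rows)
    roi_mask = df["kind"] == "roi"
    if roi_mask.any():
        df.loc[roi_mask, "p_genetics_corrected"] = correct_pvalues(
            df.loc[roi_mask, "p_genetics"].to_numpy(), correction)
    return df


def correct_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiple-comparison correction (Bonferroni or Benjamini-Hochberg)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method=method)[1]
    return out
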