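"""Per-scan connectotype models: truncated-SVD regularized multivariate
regression of each ROI on all other ROIs.

The connectotype of a scan is the M x M zero-diagonal coefficient matrix B
in which row i holds the weights b_{i,j} that predict ROI i's (prewhitened)
time course as the weighted sum of all other ROIs:

    r_hat_i(t) = sum_{j != i} b_{i,j} r_j(t)

Each row is an ordinary least-squares problem solved through the
pseudoinverse of the predictor matrix truncated to its top-k singular
values.  The regime of interest is underdetermined (more ROIs than frames),
where the truncation is the regularizer; a single shared rank k is chosen by
cross-validation over contiguous frame blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from connectokin.cohort_io import ScanTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class Connectotype:
    """Fitted connectotype: coefficients, truncation rank, frames used."""

    B: np.ndarray  # (M, M), zero diagonal; row i predicts ROI i
    rank_k: int
    fit_frames: int
    cv_errors: dict = None  # rank -> mean held-out squared error (if CV ran)

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        M = self.B.shape[0]
        if self.B.shape != (M, M):
            raise ValueError("B must be square")
        if not np.allclose(np.diag(self.B), 0.0):
            raise ValueError("diag(B) must be exactly zero")
        if not np.isfinite(self.B).all():
            raise ValueError("non-finite coefficients")
        if not (1 <= self.rank_k <= max(M - 1, 1)):
            raise ValueError(f"rank_k {self.rank_k} out of range for M={M}")

    @property
    def n_rois(self) -> int:
        return self.B.shape[0]


@dataclass
class SimilarityProfile:
    """Per-ROI prediction-observation correlations and their mean."""

    r_per_roi: np.ndarray  # length M, NaN where undefined
    valid_mask: np.ndarray  # True where correlation is defined

    @property
    def mean_r(self) -> float:
        if not self.valid_mask.any():
            return float("nan")
        return float(np.mean(self.r_per_roi[self.valid_mask]))


def _tsvd_coefficients(X: np.ndarray, Y: np.ndarray, k: int,
                       svd=None) -> np.ndarray:
    """Minimum-norm TSVD solution(s) b = V_k S_k^{-1} U_k^T Y."""
    if svd is None:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
    else:
        U, s, Vt = svd
    k = min(k, int((s > s[0] * 1e-12).sum()) if s.size else 0)
    if k == 0:
        return np.zeros((X.shape[1],) + Y.shape[1:])
    return Vt[:k].T @ ((U[:, :k].T @ Y).T / s[:k]).T


def default_rank_grid(M: int, frames: int, n: int = 10) -> np.ndarray:
    """Log-spaced candidate truncation ranks in [2, min(M-1, frames-1)]."""
    hi = min(M - 1, frames - 1)
    if hi < 2:
        return np.array([max(hi, 1)])
    grid = np.unique(np.round(np.geomspace(2, hi, n)).astype(int))
    return grid


def fit_connectotype(ts: ScanTimeSeries, rank=None, rank_grid=None,
                     cv_folds: int = 4, seed=None) -> Connectotype:
    """Fit a connectotype to the retained frames of a (prewhitened) scan.

    Parameters
    ----------
    ts : ScanTimeSeries
        Residual (prewhitened) time courses; only retained frames are used.
    rank : int, optional
        Fixed truncation rank; skips cross-validation.
    rank_grid : array-like of int, optional
        Candidate ranks for CV.  Default: 10 log-spaced values in
        [2, min(M-1, frames-1)].
    cv_folds : int
        Contiguous-block folds for rank selection; CV ties break toward the
        smaller rank (more regularization).
    seed : unused placeholder for interface symmetry (the CV is deterministic).

    Notes
    -----
    For each ROI i the predictor matrix is the retained data with column i
    removed, and its SVD is computed exactly (per-ROI refit rather than a
    shared factorization), so coefficients equal the brute-force TSVD
    least-squares solution.
    """
    X = ts.retained()
    n, M = X.shape
    if M < 3:
        raise ValueError(f"need at least 3 ROIs, have {M}")
    if n < 10:
        raise ValueError(f"need at least 10 retained frames, have {n}")
    sd = X.std(axis=0)
    if (sd == 0).any():
        roi = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"all-constant ROI column {roi}; cannot regress")
    max_rank = min(M - 1, n - 1)
    if rank is not None:
        if rank > max_rank:
            logger.warning("requested rank %d clipped to %d", rank, max_rank)
            rank = max_rank
        chosen, cv_errors = int(rank), None
    else:
        if rank_grid is None:
            grid = default_rank_grid(M, n)
        else:
            grid = np.unique(np.asarray(rank_grid, dtype=int))
            if grid.max() > max_rank:
                logger.warning("rank grid clipped to max feasible rank %d", max_rank)
                grid = np.unique(np.clip(grid, 1, max_rank))
        chosen, cv_errors = _cv_select_rank(X, grid, cv_folds)
    B = _fit_all_rows(X, chosen)
    return Connectotype(B=B, rank_k=chosen, fit_frames=n, cv_errors=cv_errors)


def _fit_all_rows(X: np.ndarray, k: int) -> np.ndarray:
    n, M = X.shape
    B = np.zeros((M, M))
    idx = np.arange(M)
    for i in range(M):
        cols = idx[idx != i]
        b = _tsvd_coefficients(X[:, cols], X[:, i], k)
        B[i, cols] = b
    return B


def _cv_select_rank(X: np.ndarray, grid: np.ndarray, cv_folds: int):
    """Shared rank minimizing total held-out squared error over contiguous
    block folds.  One SVD per (fold, ROI); all ranks evaluated incrementally
    from the same factorization."""
    n, M = X.shape
    bounds = np.linspace(0, n, cv_folds + 1).astype(int)
    kmax = int(grid.max())
    err = np.zeros(len(grid))
    idx = np.arange(M)
    for f in range(cv_folds):
        lo, hi = bounds[f], bounds[f + 1]
        test = np.zeros(n, dtype=bool)
        test[lo:hi] = True
        Xtr, Xte = X[~test], X[test]
        if Xtr.shape[0] < 3 or Xte.shape[0] < 1:
            continue
        for i in range(M):
            cols = idx[idx != i]
            U, s, Vt = np.linalg.svd(Xtr[:, cols], full_matrices=False)
            tol = s[0] * 1e-12 if s.size else 0.0
            eff = int((s > tol).sum())
            # per-component coefficient contributions c_j = v_j (u_j^T y)/s_j
            uy = U[:, :eff].T @ Xtr[:, i]
            comp_pred = (Xte[:, cols] @ Vt[:eff].T) * (uy / s[:eff])
            cum = np.cumsum(comp_pred, axis=1)
            for gi, k in enumerate(grid):
                kk = min(int(k), eff)
                pred = cum[:, kk - 1] if kk >= 1 else np.zeros(Xte.shape[0])
                err[gi] += np.sum((Xte[:, i] - pred) ** 2)
    best = int(grid[np.argmin(err)])  # argmin returns first minimum -> smaller rank
    return best, {int(k): float(e) for k, e in zip(grid, err)}


def predict_timecourses(model: Connectotype, ts: ScanTimeSeries) -> np.ndarray:
    """Predict each ROI from the others frame-wise: prediction = X @ B.T."""
    X = ts.retained()
    if X.shape[1] != model.n_rois:
        raise ValueError(
            f"scan has {X.shape[1]} ROIs but model expects {model.n_rois}"
        )
    return X @ model.B.T


def similarity(predicted: np.ndarray, observed: np.ndarray) -> SimilarityProfile:
    """Per-ROI Pearson correlation between predicted and observed columns.

    Zero-variance columns (in either input) yield an undefined correlation
    and are excluded from the mean.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed shapes differ")
    n = predicted.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 frames to correlate, have {n}")
    p = predicted - predicted.mean(axis=0)
    o = observed - observed.mean(axis=0)
    sp = np.sqrt((p ** 2).sum(axis=0))
    so = np.sqrt((o ** 2).sum(axis=0))
    valid = (sp > 0) & (so > 0)
    r = np.full(predicted.shape[1], np.nan)
    r[valid] = (p[:, valid] * o[:, valid]).sum(axis=0) / (sp[valid] * so[valid])
    r[valid] = np.clip(r[valid], -1.0, 1.0)
    return SimilarityProfile(r_per_roi=r, valid_mask=valid)


def fisher_z(r):
    """Fisher z transform atanh(r); |r| within 1e-12 of 1 is clamped."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation outside [-1, 1]")
    clamp = np.abs(r) >= 1 - 1e-12
    if np.any(clamp):
        logger.info("clamping %d correlation(s) at |r|=1 before atanh", clamp.sum())
        r = np.where(clamp, np.sign(r) * (1 - 1e-12), r)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pearson_connectivity(ts: ScanTimeSeries) -> np.ndarray:
    """Plain Pearson correlation matrix of the retained frames — the
    conventional functional-connectivity alternative to the connectotype,
    provided as a comparison utility only."""
    return np.corrcoef(ts.retained(), rowvar=False)
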