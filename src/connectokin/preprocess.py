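"""Frame censoring, band-pass filtering, nuisance regression, prewhitening.

Two preset profiles mirror the two acquisition styles the pipeline targets:

* ``oregon`` — motion censoring at FD > 0.2 mm with removal of surviving
  segments shorter than 5 frames and a 2.5-minute usable-data floor;
  detrending/nuisance regression; first-order Butterworth band pass
  0.009-0.080 Hz; AR(1) prewhitening.
* ``hcp`` — data assumed already denoised: no censoring, no prewhitening
  (order 0), optional whole-brain regression and band pass.

Filtering is applied to the full series and the censor mask consumed
afterwards, so the filter never runs across concatenated gap edges.  The
Butterworth filter runs forward-backward (zero phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from connectokin.cohort_io import ScanTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class CensorConfig:
    """Motion-censoring rule: FD threshold, minimum surviving segment length,
    and the usable-data floor below which a scan is excluded."""

    fd_threshold: float = 0.2  # mm
    min_segment: int = 5  # frames
    min_usable: float = 150.0  # seconds (2.5 min)

    def __post_init__(self):
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if self.min_usable < 0:
            raise ValueError("min_usable must be >= 0")


@dataclass
class FilterConfig:
    band_lo: float = 0.009  # Hz
    band_hi: float = 0.080  # Hz
    order: int = 1

    def validate(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if not (0 < self.band_lo < self.band_hi):
            raise ValueError(
                f"need 0 < band_lo < band_hi, got ({self.band_lo}, {self.band_hi})"
            )
        if self.band_hi >= nyquist:
            raise ValueError(
                f"band_hi {self.band_hi} Hz is at/above Nyquist {nyquist} Hz (tr={tr}s)"
            )


@dataclass
class CensorResult:
    mask: np.ndarray  # boolean, True = retained
    usable_seconds: float
    exclude: bool  # usable time below the floor


def _run_lengths(mask: np.ndarray):
    """(start, length, value) triples of maximal constant runs."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        runs.append((i, j - i, bool(mask[i])))
        i = j
    return runs


def censor_frames(fd: np.ndarray, cfg: CensorConfig = None, tr: float = 2.5) -> CensorResult:
    """Mask frames with FD above threshold, then drop surviving runs shorter
    than ``min_segment`` frames.  Scans with less than ``min_usable`` seconds
    of surviving data are flagged for exclusion (not raised)."""
    if cfg is None:
        cfg = CensorConfig()
    fd = np.asarray(fd, dtype=float)
    if (fd < 0).any():
        raise ValueError("frame displacement must be non-negative")
    mask = fd <= cfg.fd_threshold
    for start, length, value in _run_lengths(mask):
        if value and length < cfg.min_segment:
            mask[start:start + length] = False
    usable = float(mask.sum()) * tr
    exclude = usable < cfg.min_usable
    if exclude:
        logger.info("scan flagged for exclusion: %.1fs usable < %.1fs floor",
                    usable, cfg.min_usable)
    return CensorResult(mask=mask, usable_seconds=usable, exclude=exclude)


def bandpass(ts: ScanTimeSeries, cfg: FilterConfig = None) -> ScanTimeSeries:
    """Zero-phase Butterworth band pass applied to every ROI column."""
    if cfg is None:
        cfg = FilterConfig()
    cfg.validate(ts.tr)
    fs = 1.0 / ts.tr
    b, a = signal.butter(cfg.order, [cfg.band_lo, cfg.band_hi], btype="bandpass", fs=fs)
    filtered = signal.filtfilt(b, a, ts.data, axis=0)
    return ts.with_data(filtered)


def nuisance_regress(ts: ScanTimeSeries, regressors: np.ndarray | None = None) -> ScanTimeSeries:
    """Replace every ROI column by its least-squares residual against
    [intercept, linear trend, regressors].

    Only retained frames enter the fit; censored frames keep the residual of
    the same projection so dimensions are unchanged.  Collinear regressor
    columns are handled by the minimum-norm least-squares solution (a rank
    deficiency is logged).
    """
    n = ts.n_frames
    trend = np.linspace(-1.0, 1.0, n)
    design = [np.ones(n), trend]
    if regressors is not None:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != n:
            raise ValueError(
                f"regressors have {regressors.shape[0]} rows, expected {n} frames"
            )
        design.extend(regressors.T)
    X = np.column_stack(design)
    m = ts.frame_mask
    rank = np.linalg.matrix_rank(X[m])
    if rank < X.shape[1]:
        logger.warning("rank-deficient nuisance design (rank %d < %d columns); "
                       "using minimum-norm solution", rank, X.shape[1])
    beta, *_ = np.linalg.lstsq(X[m], ts.data[m], rcond=None)
    resid = ts.data - X @ beta
    return ts.with_data(resid)


def _yule_walker_ar(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by Yule-Walker (biased autocovariances)."""
    x = x - x.mean()
    n = len(x)
    acov = np.array([x[: n - k] @ x[k:] / n for k in range(order + 1)])
    if acov[0] <= 0:
        return np.zeros(order)
    R = np.array([[acov[abs(i - j)] for j in range(order)] for i in range(order)])
    r = acov[1: order + 1]
    return np.linalg.solve(R, r)


def remove_autocorrelation(ts: ScanTimeSeries, order: int = 1) -> ScanTimeSeries:
    """Prewhiten each ROI with a per-ROI AR(order) fit (Yule-Walker) and
    return the residual series; the first ``order`` frames are dropped from
    all ROIs to keep alignment.  ``order=0`` returns the input unchanged."""
    if order == 0:
        return ts
    data = ts.retained()
    n = data.shape[0]
    if n < order + 10:
        raise ValueError(f"need at least {order + 10} retained frames, have {n}")
    resid = np.empty((n - order, data.shape[1]))
    for j in range(data.shape[1]):
        x = data[:, j]
        phi = _yule_walker_ar(x, order)
        if np.abs(phi).max() >= 1.0:
            logger.warning("near-nonstationary AR fit for ROI column %d "
                           "(|phi|max=%.3f); clipping", j, np.abs(phi).max())
            phi = np.clip(phi, -0.99, 0.99)
        pred = np.zeros(n - order)
        for k, p in enumerate(phi, start=1):
            pred += p * x[order - k: n - k]
        resid[:, j] = x[order:] - pred
    return ScanTimeSeries(data=resid, tr=ts.tr, scan_id=ts.scan_id)


@dataclass
class PreprocessConfig:
    """Profile-level preprocessing configuration."""

    profile: str = "oregon"  # {"oregon", "hcp", "custom"}
    censor: CensorConfig = field(default_factory=CensorConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    ar_order: int = 1
    do_censor: bool = True
    do_filter: bool = True

    def __post_init__(self):
        if self.profile == "hcp":
            self.do_censor = False
            self.ar_order = 0
        elif self.profile not in ("oregon", "custom"):
            raise ValueError(f"unknown profile {self.profile!r}")


def preprocess_scan(ts: ScanTimeSeries, fd: np.ndarray | None = None,
                    regressors: np.ndarray | None = None,
                    cfg: PreprocessConfig | None = None):
    """Run the configured preprocessing chain on one scan.

    Order: nuisance regression (incl. detrending) -> band pass -> censor mask
    application -> AR prewhitening.  Returns ``(residual_ts, censor_result)``
    where ``censor_result`` is None when censoring is disabled; the caller is
    responsible for honouring ``censor_result.exclude``.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    censor_result = None
    mask = ts.frame_mask.copy()
    if cfg.do_censor and fd is not None:
        if len(fd) != ts.n_frames:
            raise ValueError("FD trace length must equal frame count")
        censor_result = censor_frames(fd, cfg.censor, tr=ts.tr)
        mask &= censor_result.mask
    out = nuisance_regress(ts, regressors)
    if cfg.do_filter:
        out = bandpass(out, cfg.filter)
    out = ScanTimeSeries(data=out.data, tr=ts.tr, frame_mask=mask, scan_id=ts.scan_id)
    out = ScanTimeSeries(data=out.retained(), tr=ts.tr, scan_id=ts.scan_id)
    out = remove_autocorrelation(out, cfg.ar_order)
    return out, censor_result
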