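"""Time-series denoising for spinal cord / brain fMRI.

Covers the nuisance side of the pipeline: RETROICOR-style physiological
regressors built from cardiac and respiratory phase, a CSF regressor from
the most variable CSF voxels, confound + band-pass cleaning done as a single
orthogonal projection, temporal SNR, and robust (trimmed-mean) parcellation
of voxel blocks into region time series.

The cleaning step deliberately realizes the band-pass filter as a projection
onto a discrete-cosine stop-band basis, joined with the confound columns in
ONE least-squares fit.  Applying filter and confound regression sequentially
can reintroduce removed variance; the joint projection makes the residuals
exactly orthogonal to every nuisance column and is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import RunTimeSeries
from .parcellation import ParcellationScheme

__all__ = [
    "NuisanceDesign",
    "VoxelBlock",
    "cardiac_phase",
    "respiratory_phase",
    "retroicor_design",
    "csf_regressor",
    "clean_timeseries",
    "TimeSeriesCleaner",
    "tsnr",
    "robust_parcel_mean",
]


@dataclass
class NuisanceDesign:
    """Confound design matrix: T time points x R regressor columns."""

    matrix: np.ndarray
    column_names: list[str]
    tr: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError(
                f"{self.matrix.shape[1]} columns but {len(self.column_names)} names"
            )
        zero = ~np.any(self.matrix != 0, axis=0)
        if zero.any():
            names = [self.column_names[i] for i in np.flatnonzero(zero)]
            warnings.warn(
                f"nuisance columns identically zero: {names}", stacklevel=3
            )

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class VoxelBlock:
    """Voxel-level data: V voxels x T time points with per-voxel labels."""

    data: np.ndarray
    tr: float
    labels: Optional[Sequence[str]] = None  # per-voxel region name; None for CSF

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValueError(f"voxel block needs V>=1, T>=2, got {self.data.shape}")
        if self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per voxel required")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def cardiac_phase(
    peak_times: Sequence[float], sample_times: Sequence[float]
) -> np.ndarray:
    """Cardiac phase in [0, 2*pi) at each sample time.

    Phase ramps linearly from 0 at one detected heartbeat peak to 2*pi at the
    next.  Samples outside the peak span reuse the nearest inter-peak
    interval, extrapolated periodically.
    """
    peaks = np.asarray(peak_times, dtype=float)
    t = np.asarray(sample_times, dtype=float)
    if peaks.size < 2:
        raise ValueError("need at least 2 cardiac peaks to define a phase")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak times must be strictly increasing")
    idx = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, peaks.size - 2)
    t_k = peaks[idx]
    dt = peaks[idx + 1] - peaks[idx]
    return np.mod(2 * np.pi * (t - t_k) / dt, 2 * np.pi)


def respiratory_phase(
    waveform: Sequence[float],
    times: Sequence[float],
    sample_times: Optional[Sequence[float]] = None,
    smooth_window: int = 5,
) -> np.ndarray:
    """Respiratory phase in (-pi, pi] (Glover-style histogram equalization).

    The magnitude is the empirical cumulative fraction of the amplitude
    distribution at the current amplitude, scaled by pi; the sign comes from
    the smoothed temporal derivative (inhalation positive).  Evaluated on the
    waveform's own grid, then linearly interpolated to ``sample_times`` if
    given (phase is interpolated via its sine/cosine to respect wrapping).
    """
    w = np.asarray(waveform, dtype=float)
    tw = np.asarray(times, dtype=float)
    if w.size < 2:
        raise ValueError("waveform must have at least 2 samples")
    if w.size != tw.size:
        raise ValueError("waveform and times must have equal length")
    if np.ptp(w) == 0:
        raise ValueError("constant respiratory waveform: phase undefined")
    # moving-average smoothing before differentiation to stabilize the sign
    k = max(1, min(smooth_window, w.size))
    kernel = np.ones(k) / k
    ws = np.convolve(w, kernel, mode="same")
    slope = np.gradient(ws, tw)
    sign = np.where(slope >= 0, 1.0, -1.0)
    # empirical CDF of the amplitude at each sample (fraction <= value);
    # ties share the highest rank so equal amplitudes get equal phase
    _, inv, counts = np.unique(w, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    ecdf = cum[inv] / w.size
    phase = sign * ecdf * np.pi
    if sample_times is None:
        return phase
    ts = np.asarray(sample_times, dtype=float)
    s = np.interp(ts, tw, np.sin(phase))
    c = np.interp(ts, tw, np.cos(phase))
    out = np.arctan2(s, c)
    # map -pi to +pi to keep the (-pi, pi] convention
    out[out == -np.pi] = np.pi
    return out


def retroicor_design(
    card_phase: Sequence[float],
    resp_phase: Sequence[float],
    card_order: int = 4,
    resp_order: int = 4,
    interaction_order: int = 2,
    tr: float = 0.0,
) -> NuisanceDesign:
    """Fourier expansion of cardiac/respiratory phase into nuisance regressors.

    Columns are sin/cos of m*phi_c for m = 1..card_order, sin/cos of m*phi_r
    for m = 1..resp_order, and sin/cos of (mc*phi_c + mr*phi_r) and
    (mc*phi_c - mr*phi_r) for mc, mr = 1..interaction_order.  The column
    count is 2*card_order + 2*resp_order + 4*interaction_order**2; the
    standard orders (4, 4, 2) give 32 regressors.
    """
    pc = np.asarray(card_phase, dtype=float)
    pr = np.asarray(resp_phase, dtype=float)
    if pc.shape != pr.shape:
        raise ValueError(
            f"cardiac and respiratory phases differ in length: "
            f"{pc.shape} vs {pr.shape}"
        )
    if min(card_order, resp_order, interaction_order) < 0:
        raise ValueError("expansion orders must be non-negative")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for m in range(1, card_order + 1):
        cols += [np.sin(m * pc), np.cos(m * pc)]
        names += [f"card_sin{m}", f"card_cos{m}"]
    for m in range(1, resp_order + 1):
        cols += [np.sin(m * pr), np.cos(m * pr)]
        names += [f"resp_sin{m}", f"resp_cos{m}"]
    for mc in range(1, interaction_order + 1):
        for mr in range(1, interaction_order + 1):
            for op, arg in (("plus", mc * pc + mr * pr), ("minus", mc * pc - mr * pr)):
                cols += [np.sin(arg), np.cos(arg)]
                names += [f"int_sin_{mc}c_{op}_{mr}r", f"int_cos_{mc}c_{op}_{mr}r"]
    matrix = np.column_stack(cols) if cols else np.empty((pc.size, 0))
    return NuisanceDesign(matrix=matrix, column_names=names, tr=tr)


def csf_regressor(csf: VoxelBlock, fraction: float = 0.10) -> np.ndarray:
    """Mean signal of the most temporally variable CSF voxels.

    Selects the ceil(fraction * V) voxels with the highest temporal variance
    and averages them into one T-length nuisance series.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    var = csf.data.var(axis=1, ddof=1)
    k = int(ceil(fraction * csf.n_voxels))
    top = np.argsort(var, kind="stable")[::-1][:k]
    return csf.data[np.sort(top)].mean(axis=0)


def _dct_stopband(n_timepoints: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """DCT-II basis columns whose frequencies fall outside the pass band.

    Basis vector k (k = 1..T-1) has frequency k / (2 * T * TR) Hz; the
    intercept (k = 0) is handled separately by the caller.
    """
    f_lo, f_hi = band
    t = n_timepoints
    k = np.arange(1, t)
    freqs = k / (2 * t * tr)
    keep = (freqs < f_lo) | (freqs > f_hi)
    ks = k[keep]
    grid = np.arange(t)
    # orthonormal DCT-II atoms
    basis = np.cos(np.pi * np.outer(grid + 0.5, ks) / t) * np.sqrt(2.0 / t)
    return basis


def clean_timeseries(
    data: np.ndarray,
    confounds: Optional[NuisanceDesign | np.ndarray] = None,
    band: tuple[float, float] = (0.01, 0.13),
    tr: float = 2.08,
) -> np.ndarray:
    """Remove confounds and out-of-band frequencies in one joint projection.

    A discrete-cosine basis spanning all frequencies outside ``band`` is
    concatenated with the confound columns and an intercept; the joint
    least-squares fit is removed in a single step, so the residuals are
    orthogonal to every nuisance column and the operation is idempotent.

    Parameters
    ----------
    data
        channels x T array (regions, voxels or slices-worth of channels).
    confounds
        Optional design (T x R).  Rank deficiency is handled by the
        pseudoinverse (minimum-norm fit).
    band
        (f_lo, f_hi) pass band in Hz; frequencies outside it are removed.
    tr
        Sampling interval in seconds.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    t = x.shape[1]
    f_lo, f_hi = band
    nyquist = 1.0 / (2.0 * tr)
    if not 0 <= f_lo < f_hi <= nyquist + 1e-12:
        raise ValueError(
            f"band {band} must satisfy 0 <= f_lo < f_hi <= Nyquist ({nyquist:.4f} Hz)"
        )
    pieces = [np.ones((t, 1))]
    stop = _dct_stopband(t, tr, band)
    if stop.shape[1]:
        pieces.append(stop)
    if confounds is not None:
        cmat = confounds.matrix if isinstance(confounds, NuisanceDesign) else confounds
        cmat = np.atleast_2d(np.asarray(cmat, dtype=float))
        if cmat.shape[0] != t:
            raise ValueError(
                f"confounds have {cmat.shape[0]} rows but data has {t} time points"
            )
        pieces.append(cmat)
    design = np.hstack(pieces)
    if design.shape[1] >= t:
        raise ValueError(
            f"nuisance space ({design.shape[1]} columns) is as large as the "
            f"series (T={t}); nothing would remain"
        )
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


class TimeSeriesCleaner(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`clean_timeseries`.

    Operates on arrays shaped channels x T (``transform`` cleans rows).
    Stateless — ``fit`` only validates parameters — but provided so cleaning
    composes with sklearn pipelines.

    Parameters
    ----------
    band : tuple of float, default (0.01, 0.13)
        Pass band in Hz.
    tr : float, default 2.08
        Sampling interval in seconds.
    confounds : NuisanceDesign or array, optional
        T x R confound matrix removed jointly with the filter.
    """

    def __init__(self, band=(0.01, 0.13), tr=2.08, confounds=None):
        self.band = band
        self.tr = tr
        self.confounds = confounds

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_timepoints_ = X.shape[1]
        return self

    def transform(self, X):
        return clean_timeseries(X, confounds=self.confounds, band=self.band, tr=self.tr)


def tsnr(block: VoxelBlock) -> np.ndarray:
    """Temporal SNR per voxel: temporal mean / temporal std (ddof=1).

    Zero-variance voxels yield +/-inf (sign of the mean), flagged by a
    warning rather than an exception.
    """
    mean = block.data.mean(axis=1)
    std = block.data.std(axis=1, ddof=1)
    if np.any(std == 0):
        warnings.warn("zero-variance voxel(s): tSNR is infinite there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mean / std
    return out


def robust_parcel_mean(
    block: VoxelBlock,
    scheme: ParcellationScheme,
    trim: tuple[float, float] = (0.05, 0.95),
    subject_id: str = "",
    run_id: str = "",
) -> RunTimeSeries:
    """Average voxels into region time series with per-time-point trimming.

    At each time point, voxel values below the lower or above the upper
    percentile of that region's cross-voxel distribution are excluded before
    averaging.  Regions with fewer than 5 voxels use a plain mean (trimming
    at 5-95% is vacuous below that size).
    """
    if block.labels is None:
        raise ValueError("voxel block has no region labels")
    lo, hi = trim
    labels = np.asarray(block.labels)
    rows = []
    missing = [name for name in scheme.names if not np.any(labels == name)]
    if missing:
        raise ValueError(f"regions with zero voxels: {missing}")
    for name in scheme.names:
        vox = block.data[labels == name]
        if vox.shape[0] < 5:
            rows.append(vox.mean(axis=0))
            continue
        p_lo = np.percentile(vox, 100 * lo, axis=0)
        p_hi = np.percentile(vox, 100 * hi, axis=0)
        # the trim band always contains the median, so the mask is never empty
        mask = (vox >= p_lo) & (vox <= p_hi)
        rows.append(np.nanmean(np.where(mask, vox, np.nan), axis=0))
    data = np.vstack(rows)
    return RunTimeSeries(
        data=data, tr=block.tr, scheme=scheme, subject_id=subject_id, run_id=run_id
    )
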