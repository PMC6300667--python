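"""Time-series conditioning applied before correlation analyses.

The pipeline order is fixed: (1) despike at 2.5 SD, (2) band-pass
0.01-0.1 Hz, (3) linear + quadratic detrending, (4) nuisance regression
(six motion estimates and their temporal derivatives, ventricle and
white-matter signals; the global mean signal is deliberately not removed).
Rest runs additionally have their initial 21.6 s dropped before these steps,
and pulvinar voxel data are spatially smoothed (4 mm FWHM) within the mask
afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import ndimage, signal

from .datatypes import SubjectDataset

logger = logging.getLogger(__name__)

__all__ = [
    "despike",
    "bandpass",
    "detrend_poly",
    "nuisance_regress",
    "motion_derivatives",
    "smooth_gaussian",
    "drop_initial",
    "preprocess_series",
    "preprocess_dataset",
]


def despike(series: np.ndarray, threshold_sd: float = 2.5) -> np.ndarray:
    """Clip samples deviating more than `threshold_sd` SDs from the mean.

    Centre and scale are estimated by iterative sigma-clipping (mean and SD
    of the non-outlier samples, to convergence) so a spike cannot inflate
    its own clipping envelope; spikes are shrunk to the envelope edge (a
    simple clip with the same intent as smooth-fit despiking) and all other
    samples pass through unchanged.  Works on 1-D series or
    (n_series, n_timepoints) arrays, per-row statistics.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("despike needs at least 3 samples")
    flat = np.atleast_2d(x)
    inlier = np.ones_like(flat, dtype=bool)
    center = flat.mean(axis=-1, keepdims=True)
    scale = flat.std(axis=-1, keepdims=True)
    for _ in range(10):                 # sigma-clip to convergence
        with np.errstate(invalid="ignore"):
            new = np.abs(flat - center) <= threshold_sd * scale
        new |= scale == 0               # zero-spread rows keep all samples
        if np.array_equal(new, inlier):
            break
        inlier = new
        n_in = inlier.sum(axis=-1, keepdims=True)
        center = (flat * inlier).sum(axis=-1, keepdims=True) / n_in
        dev = (flat - center) * inlier
        scale = np.sqrt((dev**2).sum(axis=-1, keepdims=True) / n_in)
    zero_var = scale == 0
    if np.any(zero_var):
        logger.info("despike: %d zero-spread series returned unchanged",
                    int(zero_var.sum()))
    env = np.where(zero_var, np.inf, threshold_sd * scale)
    out = np.clip(flat, center - env, center + env)
    return out.reshape(x.shape)


def bandpass(series: np.ndarray, tr_seconds: float,
             low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    Retains 0.01-0.1 Hz by default and removes the mean (DC is outside the
    band).  Fails if the band exceeds the Nyquist frequency.
    """
    x = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:g}) "
            f"for TR {tr_seconds} s")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, x - x.mean(axis=-1, keepdims=True),
                              axis=-1)


def detrend_poly(series: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a polynomial trend (default linear + quadratic) by least
    squares; the residual is orthogonal to all polynomials up to `order`."""
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[-1]
    if n <= order + 1:
        raise ValueError(f"series length {n} too short for order {order}")
    t = np.linspace(-1.0, 1.0, n)
    basis = np.polynomial.legendre.legvander(t, order)
    coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
    out = x - (basis @ coef).T
    return out.reshape(np.asarray(series, dtype=float).shape)


def motion_derivatives(motion: np.ndarray) -> np.ndarray:
    """Temporal derivatives of motion regressors by first differences, with
    a zero-padded first sample."""
    motion = np.asarray(motion, dtype=float)
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    return deriv


def nuisance_regress(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Regress nuisance columns (plus an intercept) out of the series.

    The global mean signal is intentionally not part of the default nuisance
    set.  The residual is orthogonal to every regressor column.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    R = np.asarray(regressors, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if R.shape[0] != x.shape[-1]:
        raise ValueError(
            f"regressors have {R.shape[0]} rows, series has {x.shape[-1]} "
            "timepoints")
    X = np.column_stack([np.ones(R.shape[0]), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.T)
        pairs = [(i, j) for i in range(X.shape[1])
                 for j in range(i + 1, X.shape[1])
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(
            f"nuisance regressor matrix rank deficient (rank {rank} < "
            f"{X.shape[1]}); collinear column pairs: {pairs}")
    coef, *_ = np.linalg.lstsq(X, x.T, rcond=None)
    out = x - (X @ coef).T
    return out.reshape(np.asarray(series, dtype=float).shape)


def drop_initial(series: np.ndarray, tr_seconds: float,
                 seconds: float = 21.6) -> np.ndarray:
    """Remove the first ``floor(seconds / tr)`` samples (scanner-onset
    transient).  Fractional sample counts are floored and logged."""
    x = np.asarray(series, dtype=float)
    exact = seconds / tr_seconds
    n_drop = int(np.floor(exact + 1e-9))
    if abs(exact - n_drop) > 1e-9:
        logger.info("drop_initial: %.3f s is %.3f samples; flooring to %d",
                    seconds, exact, n_drop)
    if n_drop >= x.shape[-1]:
        raise ValueError(
            f"dropping {n_drop} samples leaves nothing of a length-"
            f"{x.shape[-1]} series")
    return x[..., n_drop:]


def smooth_gaussian(dataset: SubjectDataset, fwhm_mm: float = 4.0,
                    ) -> SubjectDataset:
    """Spatial Gaussian smoothing (sigma = FWHM / 2*sqrt(2 ln 2)) within the
    mask, per timepoint and per hemisphere.

    Mask-normalised: the kernel is renormalised over in-mask voxels so a
    spatially constant field passes through unchanged.  Requires voxels on a
    regular lattice.
    """
    if fwhm_mm <= 0:
        return dataset
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = dataset.voxel_series.copy()
    for hemi in np.unique(dataset.hemisphere):
        sel = dataset.hemisphere == hemi
        coords = dataset.voxel_coords_mm[sel]
        idx, spacing, shape = _lattice_index(coords)
        sigma_vox = sigma_mm / spacing
        mask = np.zeros(shape, dtype=float)
        mask[tuple(idx.T)] = 1.0
        norm = ndimage.gaussian_filter(mask, sigma=sigma_vox)
        T = out.shape[1]
        vol = np.zeros(shape + (T,))
        vol[tuple(idx.T)] = out[sel]
        sm = ndimage.gaussian_filter(vol, sigma=tuple(sigma_vox) + (0.0,))
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = sm / norm[..., None]
        out[sel] = sm[tuple(idx.T)]
    return replace(dataset, voxel_series=out)


def _lattice_index(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Integer lattice indices, per-axis spacing, and grid shape for voxel
    coordinates; fails on an irregular lattice."""
    idx = np.empty_like(coords, dtype=int)
    spacing = np.empty(3)
    for ax in range(3):
        vals = np.unique(coords[:, ax])
        if len(vals) > 1:
            steps = np.diff(vals)
            step = steps.min()
            if not np.allclose(steps % step, 0, atol=1e-6):
                raise ValueError(
                    f"irregular voxel lattice along axis {ax}: spacings "
                    f"{np.unique(np.round(steps, 6))}")
        else:
            step = 1.0
        spacing[ax] = step
        pos = np.round((coords[:, ax] - vals[0]) / step)
        if not np.allclose(pos, np.round(pos), atol=1e-6):
            raise ValueError(f"irregular voxel lattice along axis {ax}")
        idx[:, ax] = pos.astype(int)
    shape = tuple(idx.max(axis=0) + 1)
    return idx, spacing, shape


# ---------------------------------------------------------------------------
# Composed pipeline
# ---------------------------------------------------------------------------

def preprocess_series(series: np.ndarray, tr_seconds: float,
                      nuisance: np.ndarray | None = None,
                      despike_sd: float = 2.5,
                      low_hz: float = 0.01, high_hz: float = 0.1,
                      detrend_order: int = 2,
                      drop_seconds: float = 0.0,
                      motion_columns: int = 6) -> np.ndarray:
    """Despike -> band-pass -> detrend -> nuisance regression, optionally
    preceded by dropping initial samples.

    The first `motion_columns` nuisance columns are treated as motion
    estimates and augmented with their first-difference temporal
    derivatives.
    """
    x = np.asarray(series, dtype=float)
    if drop_seconds > 0:
        x = drop_initial(x, tr_seconds, drop_seconds)
    x = despike(x, despike_sd)
    x = bandpass(x, tr_seconds, low_hz, high_hz)
    x = detrend_poly(x, detrend_order)
    if nuisance is not None and nuisance.shape[1] > 0:
        R = np.asarray(nuisance, dtype=float)
        if drop_seconds > 0:
            R = drop_initial(R.T, tr_seconds, drop_seconds).T
        if motion_columns > 0:
            m = min(motion_columns, R.shape[1])
            R = np.column_stack([R, motion_derivatives(R[:, :m])])
        x = nuisance_regress(x, R)
    logger.info("preprocess_series: %s -> %s", np.shape(series), x.shape)
    return x


def preprocess_dataset(dataset: SubjectDataset,
                       drop_seconds: float = 21.6,
                       smooth_fwhm_mm: float = 4.0,
                       **kwargs) -> SubjectDataset:
    """Full conditioning of a subject's voxel data: temporal steps, then
    spatial smoothing within the mask."""
    cleaned = preprocess_series(dataset.voxel_series, dataset.tr_seconds,
                                nuisance=dataset.nuisance,
                                drop_seconds=drop_seconds, **kwargs)
    ds = replace(dataset, voxel_series=cleaned, nuisance=dataset.nuisance)
    if smooth_fwhm_mm > 0:
        ds = smooth_gaussian(ds, smooth_fwhm_mm)
    return ds
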