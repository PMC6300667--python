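"""Block-design GLM, d-prime tuning indices, and group statistics.

The laterality / attentional-modulation analysis models each stimulus
condition as a square wave matching the block timing, convolved with a
hemodynamic response function, alongside baseline, drift and motion
regressors.  Contralateral tuning and attentional modulation are summarised
per voxel (or ROI) with the d-prime index

    d' = (mu_a - mu_b) / sqrt((sd_a^2 + sd_b^2) / 2)

computed from per-block response means.  Category-selective ROIs are defined
by a leave-one-subject-out pseudo-group contrast so that no subject's own
data enters its ROI definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "hrf_kernel",
    "condition_regressors",
    "build_design",
    "DesignMatrix",
    "fit_glm",
    "GLMResults",
    "dprime_index",
    "block_response_stats",
    "loo_category_roi",
    "group_stats",
]


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

def hrf_kernel(tr_seconds: float, kind: str = "double_gamma",
               duration_seconds: float = 32.0,
               peak_seconds: float = 6.0, undershoot_seconds: float = 16.0,
               undershoot_ratio: float = 6.0) -> np.ndarray:
    """Sampled HRF kernel, normalised to unit peak.

    ``double_gamma`` is the canonical difference of two gamma densities with
    the positive lobe peaking at `peak_seconds` and the undershoot at
    `undershoot_seconds` (gamma scale fixed at 1 s, so the mode of a lobe is
    shape - 1).  ``delta`` returns the identity kernel, useful for tests.
    """
    if kind == "delta":
        return np.array([1.0])
    if kind != "double_gamma":
        raise ValueError(f"unknown HRF kind {kind!r}")
    t = np.arange(0.0, duration_seconds + 1e-9, tr_seconds)
    a1, a2 = peak_seconds + 1.0, undershoot_seconds + 1.0

    def gamma_pdf(x, shape):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((shape - 1) * np.log(x[pos]) - x[pos]
                          - special.gammaln(shape))
        return out

    h = gamma_pdf(t, a1) - gamma_pdf(t, a2) / undershoot_ratio
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("HRF kernel degenerate: increase duration or lower TR")
    return h / peak


def condition_regressors(block_table: pd.DataFrame, tr_seconds: float,
                         n_timepoints: int,
                         hrf_kind: str = "double_gamma") -> pd.DataFrame:
    """Square-wave condition regressors convolved with the HRF.

    `block_table` needs columns ``onset`` (s), ``duration`` (s),
    ``condition``.  The square wave is 1 at sample k when
    onset <= k*TR < onset + duration.
    """
    required = {"onset", "duration", "condition"}
    missing = required - set(block_table.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    t = np.arange(n_timepoints) * tr_seconds
    run_length = n_timepoints * tr_seconds
    if ((block_table["onset"] < 0).any()
            or (block_table["onset"] + block_table["duration"] > run_length + 1e-9).any()):
        raise ValueError("block extends outside the run")
    kernel = hrf_kernel(tr_seconds, kind=hrf_kind)
    cols = {}
    for cond, grp in block_table.groupby("condition", sort=True):
        box = np.zeros(n_timepoints)
        intervals = sorted(zip(grp["onset"], grp["duration"]))
        for (o1, d1), (o2, _) in zip(intervals, intervals[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError(f"overlapping blocks for condition {cond!r}")
        for onset, dur in intervals:
            box[(t >= onset - 1e-9) & (t < onset + dur - 1e-9)] = 1.0
        cols[str(cond)] = np.convolve(box, kernel)[:n_timepoints]
    return pd.DataFrame(cols, columns=sorted(cols))


@dataclass
class DesignMatrix:
    """Named design matrix for the block-design GLM."""

    frame: pd.DataFrame          # n_timepoints x n_regressors
    condition_names: list
    tr_seconds: float

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    def column_index(self, name: str) -> int:
        return list(self.frame.columns).index(name)


def build_design(block_table: pd.DataFrame, tr_seconds: float,
                 n_timepoints: int, hrf_kind: str = "double_gamma",
                 nuisance: np.ndarray | None = None,
                 drift: bool = True) -> DesignMatrix:
    """Assemble the GLM design: HRF-convolved conditions, baseline, linear
    drift, and optional nuisance (e.g. motion) columns."""
    if len(block_table):
        conds = condition_regressors(block_table, tr_seconds, n_timepoints,
                                     hrf_kind=hrf_kind)
    else:
        conds = pd.DataFrame(index=range(n_timepoints))
    frame = conds.copy()
    frame["baseline"] = 1.0
    if drift:
        tt = np.linspace(-1.0, 1.0, n_timepoints)
        frame["drift_linear"] = tt
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_timepoints:
            raise ValueError("nuisance rows must match n_timepoints")
        for j in range(nuisance.shape[1]):
            frame[f"nuisance_{j}"] = nuisance[:, j]
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(frame=frame, condition_names=list(conds.columns),
                        tr_seconds=tr_seconds)


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------

@dataclass
class GLMResults:
    """Ordinary least-squares fit of a design to voxel time series."""

    betas: np.ndarray            # n_voxels x n_regressors
    sigma2: np.ndarray           # n_voxels residual variance (unbiased)
    df_resid: int
    design: DesignMatrix
    _xtx_inv: np.ndarray

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.design.column_index(name)]

    def contrast(self, weights: dict) -> np.ndarray:
        """Per-voxel contrast value sum_k w_k * beta_k."""
        c = self._contrast_vector(weights)
        return self.betas @ c

    def contrast_t(self, weights: dict) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel t statistic and two-tailed p for a contrast."""
        c = self._contrast_vector(weights)
        est = self.betas @ c
        var_scale = float(c @ self._xtx_inv @ c)
        se = np.sqrt(self.sigma2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = est / se
        pval = 2.0 * stats.t.sf(np.abs(tval), self.df_resid)
        return tval, pval

    def _contrast_vector(self, weights: dict) -> np.ndarray:
        c = np.zeros(self.betas.shape[1])
        for name, w in weights.items():
            c[self.design.column_index(name)] = w
        return c


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMResults:
    """Fit the GLM by ordinary least squares to every voxel.

    `data` is (n_voxels, n_timepoints); residuals are orthogonal to the
    design columns by construction.
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    X = design.matrix
    if Y.shape[1] != X.shape[0]:
        raise ValueError(
            f"data has {Y.shape[1]} timepoints but design has {X.shape[0]}")
    betas, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = Y.T - X @ betas
    df = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / max(df, 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    return GLMResults(betas=betas.T, sigma2=sigma2, df_resid=df,
                      design=design, _xtx_inv=xtx_inv)


# ---------------------------------------------------------------------------
# d-prime tuning index
# ---------------------------------------------------------------------------

def dprime_index(mu_a: float, sd_a: float, mu_b: float, sd_b: float) -> float:
    """d' = (mu_a - mu_b) / sqrt((sd_a^2 + sd_b^2) / 2).

    Standardised response difference between two conditions; antisymmetric in
    (a, b) and invariant to a common positive rescaling of all arguments.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0:
        raise ValueError("d-prime undefined: both condition SDs are zero")
    return float((mu_a - mu_b) / pooled)


def block_response_stats(data: np.ndarray, block_table: pd.DataFrame,
                         tr_seconds: float,
                         lag_seconds: float = 6.0) -> dict:
    """Per-condition mean and SD of per-block responses.

    The response to a block is the mean signal in a window of the block's
    duration, lagged `lag_seconds` (the HRF peak) after block onset.  Returns
    {condition: (mu, sd)} with mu, sd arrays of shape (n_voxels,); SD is
    across blocks (ddof=1, zero if a condition has a single block).
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    n_t = Y.shape[1]
    out = {}
    for cond, grp in block_table.groupby("condition", sort=True):
        block_means = []
        for onset, dur in zip(grp["onset"], grp["duration"]):
            lo = int(round((onset + lag_seconds) / tr_seconds))
            hi = int(round((onset + lag_seconds + dur) / tr_seconds))
            lo, hi = max(lo, 0), min(hi, n_t)
            if hi <= lo:
                continue
            block_means.append(Y[:, lo:hi].mean(axis=1))
        if not block_means:
            raise ValueError(f"no usable response window for condition {cond!r}")
        M = np.stack(block_means)
        sd = M.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(Y.shape[0])
        out[str(cond)] = (M.mean(axis=0), sd)
    return out


# ---------------------------------------------------------------------------
# Leave-one-out category ROI analysis
# ---------------------------------------------------------------------------

def _precision_weighted_z(contrasts: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Inverse-variance-weighted one-sample z across subjects (per voxel)."""
    w = 1.0 / np.maximum(variances, 1e-300)
    est = np.sum(w * contrasts, axis=0) / np.sum(w, axis=0)
    se = 1.0 / np.sqrt(np.sum(w, axis=0))
    return est / se


def loo_category_roi(contrast_maps: np.ndarray, contrast_vars: np.ndarray,
                     category_betas: dict, roi_mask: np.ndarray,
                     grid_index: np.ndarray | None = None,
                     q: float = 0.05) -> pd.DataFrame:
    """Leave-one-subject-out category ROI analysis.

    For each subject an n-1 pseudo-group contrast map is computed from the
    remaining subjects with an inverse-variance-weighted one-sample z test;
    the ROI is the FDR-significant (Benjamini-Hochberg, `q`) positive voxels
    within `roi_mask`, tie-broken to the largest connected cluster when
    `grid_index` (integer voxel indices, n_voxels x 3) is given.  Mean betas
    per category are then read from the held-out subject inside that ROI.

    Parameters
    ----------
    contrast_maps, contrast_vars : ndarray (n_subjects, n_voxels)
        Per-subject contrast estimates (e.g. face minus scene) and their
        estimated variances.
    category_betas : dict category -> ndarray (n_subjects, n_voxels)
    roi_mask : bool ndarray (n_voxels,)
        Anatomical search region (e.g. the posterior-medial mask octant).
    """
    C = np.asarray(contrast_maps, dtype=float)
    V = np.asarray(contrast_vars, dtype=float)
    n_subj = C.shape[0]
    if n_subj < 3:
        raise ValueError("leave-one-out ROI analysis needs >= 3 subjects")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    rows = []
    for s in range(n_subj):
        keep = np.arange(n_subj) != s
        z = _precision_weighted_z(C[keep], V[keep])
        p = 2.0 * stats.norm.sf(np.abs(z))
        rej = np.zeros_like(roi_mask)
        idx = np.flatnonzero(roi_mask)
        if idx.size:
            rej_in, _, _, _ = multipletests(p[idx], alpha=q, method="fdr_bh")
            rej[idx] = rej_in
        roi = rej & (z > 0) & roi_mask
        if not roi.any():
            raise ValueError(
                f"empty ROI for held-out subject {s} at FDR q={q}")
        if grid_index is not None:
            roi = _largest_cluster(roi, np.asarray(grid_index))
        row = {"subject": s, "roi_size": int(roi.sum())}
        for cat, B in category_betas.items():
            row[str(cat)] = float(np.asarray(B)[s, roi].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _largest_cluster(roi: np.ndarray, grid_index: np.ndarray) -> np.ndarray:
    shape = tuple(grid_index.max(axis=0) + 1)
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(grid_index[roi].T)] = True
    labels, n = ndimage.label(vol)
    if n <= 1:
        return roi
    sizes = ndimage.sum_labels(vol, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    keep = labels[tuple(grid_index.T)] == best
    return roi & keep


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def group_stats(values: np.ndarray, test: str = "one_sample_t",
                correction: str = "fdr_bh", q: float = 0.05,
                fisher: bool = False, popmean: float = 0.0) -> pd.DataFrame:
    """Group-level test across subjects per voxel / entry.

    `values` is (n_subjects, n_entries) or (n_subjects,).  Correlation inputs
    should set ``fisher=True`` to be Fisher z-transformed before testing.
    Returns a table with mean, statistic, two-tailed p, BH-adjusted q,
    rejection flag, and Cohen's d.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("group statistics need at least 2 subjects")
    if fisher:
        X = np.arctanh(np.clip(X, -1 + 1e-12, 1 - 1e-12))
        popmean = np.arctanh(popmean)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd <= 1e-12 * (np.abs(mean) + 1.0)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} entries constant across "
                      "subjects; p undefined there", stacklevel=2)
    if test == "one_sample_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            stat, p = stats.ttest_1samp(X, popmean, axis=0)
    elif test == "wilcoxon":
        stat = np.empty(X.shape[1])
        p = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            d = X[:, j] - popmean
            if np.all(d == 0):
                stat[j], p[j] = np.nan, np.nan
                continue
            res = stats.wilcoxon(d)
            stat[j], p[j] = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    stat = np.where(constant, np.nan, stat)
    p = np.where(constant, np.nan, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        cohen_d = (mean - popmean) / sd
    p_use = np.where(np.isfinite(p), p, 1.0)
    if correction == "fdr_bh":
        reject, q_val, _, _ = multipletests(p_use, alpha=q, method="fdr_bh")
    elif correction is None or correction == "none":
        reject, q_val = p_use <= q, p_use
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return pd.DataFrame({
        "mean": np.tanh(mean) if fisher else mean,
        "stat": stat, "p": p, "q": q_val, "reject": reject,
        "cohen_d": cohen_d,
    })
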