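"""Inter-subject correlation (ISC) and the intact-vs-scrambled contrast.

ISC measures stimulus-locked, stereotyped processing: each subject's movie
response is correlated with the average response of all other subjects.
Regions with long temporal receptive windows lose consistency when the movie
is presented with its segments temporally scrambled, so the intact minus
scrambled ISC difference localises context-integrating tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["average_repetitions", "leave_one_out_isc", "ISCMap",
           "isc_timescale_contrast", "movie_isc_summary"]


def average_repetitions(runs: np.ndarray) -> np.ndarray:
    """Pointwise mean over repetitions (leading axis).

    `runs` has shape (n_repetitions, ..., n_timepoints); all repetitions must
    share one length.
    """
    runs = np.asarray(runs, dtype=float)
    if runs.ndim < 2:
        raise ValueError("expected (n_repetitions, ..., n_timepoints)")
    return runs.mean(axis=0)


@dataclass
class ISCMap:
    """Leave-one-out inter-subject correlations for one condition.

    ``per_subject`` is (n_subjects, n_entries) with NaN where a subject's
    series was constant (excluded and logged); ``mean`` averages the defined
    values per entry.
    """

    per_subject: np.ndarray
    mean: np.ndarray
    n_subjects: int
    condition: str = ""


def leave_one_out_isc(series: np.ndarray, condition: str = "") -> ISCMap:
    """Leave-one-out ISC: r_i = corr(subject i, mean of the others).

    `series` is (n_subjects, n_entries, n_timepoints) (or
    (n_subjects, n_timepoints) for a single entry).  The reported map is the
    arithmetic mean of the per-subject r values.
    """
    X = np.asarray(series, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[:, None, :]
    n_subj = X.shape[0]
    if n_subj < 2:
        raise ValueError("ISC needs at least 2 subjects")
    total = X.sum(axis=0)
    r = np.empty(X.shape[:2])
    for i in range(n_subj):
        others = (total - X[i]) / (n_subj - 1)
        r[i] = _rowwise_corr(X[i], others)
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        logger.info("leave_one_out_isc: %d undefined (constant-series) "
                    "subject/entry correlations excluded", n_bad)
    mean = np.nanmean(r, axis=0)
    return ISCMap(per_subject=r, mean=mean, n_subjects=n_subj,
                  condition=condition)


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a**2).sum(-1) * (b**2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(-1) / denom
    r[denom == 0] = np.nan
    return r


def isc_timescale_contrast(isc_intact: ISCMap, isc_scrambled: ISCMap,
                           threshold: float = 0.15) -> dict:
    """Intact minus scrambled difference map with threshold labels.

    ``long_timescale``: difference > threshold (context-integrating);
    ``consistent``: mean intact r > threshold (stimulus-locked at all).
    """
    if isc_intact.mean.shape != isc_scrambled.mean.shape:
        raise ValueError("condition maps cover different voxel sets")
    if isc_intact.n_subjects != isc_scrambled.n_subjects:
        raise ValueError("condition maps from different subject counts")
    diff = isc_intact.mean - isc_scrambled.mean
    return {
        "difference": diff,
        "long_timescale": diff > threshold,
        "consistent": isc_intact.mean > threshold,
        "threshold": threshold,
    }


def movie_isc_summary(movie_dataset, threshold: float = 0.15) -> dict:
    """End-to-end ISC analysis of a simulated movie dataset.

    Averages repetitions within subject per condition, computes leave-one-out
    ISC per region and condition over voxels, and applies the timescale
    contrast.  Returns per-region mean intact / scrambled ISC, the
    difference, and the threshold labels.
    """
    out = {}
    for region in movie_dataset.responses["intact"]:
        maps = {}
        for cond in ("intact", "scrambled"):
            resp = movie_dataset.responses[cond][region]
            avg = average_repetitions(np.swapaxes(resp, 0, 1))
            maps[cond] = leave_one_out_isc(avg, condition=cond)
        contrast = isc_timescale_contrast(maps["intact"], maps["scrambled"],
                                          threshold)
        out[region] = {
            "isc_intact": float(np.nanmean(maps["intact"].mean)),
            "isc_scrambled": float(np.nanmean(maps["scrambled"].mean)),
            "difference": float(np.nanmean(contrast["difference"])),
            "long_timescale": bool(contrast["long_timescale"].mean() > 0.5),
            "consistent": bool(contrast["consistent"].mean() > 0.5),
            "maps": maps,
        }
    return out
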