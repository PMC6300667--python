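"""Two-step connectivity-fingerprint analysis of pulvino-cortical coupling.

Step one correlates, within each subject, the mean time series of every
cortical area with every other area (the *cortical correlation profile*) and
with every pulvinar voxel.  Step two correlates each voxel's profile with
the leave-one-subject-out pseudo-group profile of each area, yielding one
voxel map per cortical area — the *pulvino-cortical connectivity*.  Group
maps are formed and tested in Fisher-z space with BH-FDR correction.

The user-facing surface is :class:`PulvinoCorticalModel` (built from subject
datasets and an :class:`~pulvicon.datatypes.AreaSet`) whose :meth:`fit`
returns a :class:`PulvinoCorticalResults` carrying the per-subject and group
maps, their statistics, and the downstream network-structure summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AreaSet, SubjectDataset
from .preprocess import preprocess_dataset, preprocess_series
from .taskglm import group_stats

logger = logging.getLogger(__name__)

__all__ = [
    "area_profile",
    "voxel_profiles",
    "pseudo_group_profile",
    "profile_similarity_map",
    "ConnectivityMaps",
    "group_connectivity",
    "split_half_reliability",
    "PulvinoCorticalModel",
    "PulvinoCorticalResults",
]

_ATANH_CLIP = 1.0 - 1e-12


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = np.sqrt((x**2).sum(-1, keepdims=True))
    return x / sd


def area_profile(area_series: np.ndarray, names: list | None = None,
                 ) -> np.ndarray:
    """Pearson correlation of every cortical area with every other (one
    subject): the cortical correlation profile matrix."""
    X = np.asarray(area_series, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("area profiles need at least 3 timepoints")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        label = [names[i] for i in bad] if names is not None else bad.tolist()
        raise ValueError(f"constant area series: {label}")
    return np.corrcoef(X)


def voxel_profiles(voxel_series: np.ndarray, area_series: np.ndarray,
                   ) -> np.ndarray:
    """Correlation of each pulvinar voxel with each cortical area's mean
    series; rows are voxels, columns areas.  Voxels with zero variance get
    NaN rows (masked downstream)."""
    V = np.asarray(voxel_series, dtype=float)
    A = np.asarray(area_series, dtype=float)
    if V.shape[1] != A.shape[1]:
        raise ValueError("voxel and area series must share the time axis")
    sd_a = A.std(axis=1)
    if np.any(sd_a == 0):
        raise ValueError(
            f"constant area series at rows {np.flatnonzero(sd_a == 0).tolist()}")
    vz = V - V.mean(axis=1, keepdims=True)
    sv = np.sqrt((vz**2).sum(1, keepdims=True))
    degenerate = sv[:, 0] == 0
    sv[degenerate] = 1.0
    R = (vz / sv) @ _standardize(A).T
    R[degenerate] = np.nan
    if degenerate.any():
        logger.info("voxel_profiles: %d zero-variance voxels masked",
                    int(degenerate.sum()))
    return R


def pseudo_group_profile(profiles: dict, exclude_subject: str) -> np.ndarray:
    """Leave-one-subject-out group average cortical profile.

    Entrywise Fisher-z mean over the included subjects, back-transformed;
    the excluded subject contributes nothing.  The unit diagonal is
    preserved exactly.
    """
    keep = [s for s in profiles if s != exclude_subject]
    if not keep:
        raise ValueError("excluding this subject leaves no subjects")
    Z = np.mean([np.arctanh(np.clip(profiles[s], -_ATANH_CLIP, _ATANH_CLIP))
                 for s in keep], axis=0)
    out = np.tanh(Z)
    np.fill_diagonal(out, 1.0)
    return out


def profile_similarity_map(vox_profiles: np.ndarray,
                           group_profile: np.ndarray,
                           include_self: bool = False) -> np.ndarray:
    """Second-order similarity: per (voxel, area), the Pearson r between the
    voxel's area-correlation vector and the area's pseudo-group
    area-correlation vector.

    By default the seed area's own entry (its trivial self-correlation of 1)
    is excluded from both vectors; ``include_self=True`` keeps it.
    Voxels with any undefined profile entry are masked out (NaN).
    """
    P = np.asarray(vox_profiles, dtype=float)
    G = np.asarray(group_profile, dtype=float)
    n_areas = G.shape[0]
    if P.shape[1] != n_areas:
        raise ValueError("area ordering mismatch between profile inputs")
    bad_vox = ~np.all(np.isfinite(P), axis=1)
    if bad_vox.any():
        logger.info("profile_similarity_map: %d voxels with undefined "
                    "profile entries masked", int(bad_vox.sum()))
    out = np.full((P.shape[0], n_areas), np.nan)
    for a in range(n_areas):
        cols = np.arange(n_areas) if include_self else \
            np.delete(np.arange(n_areas), a)
        g = G[a, cols]
        v = P[:, cols]
        gz = g - g.mean()
        gnorm = np.sqrt((gz**2).sum())
        vz = v - v.mean(axis=1, keepdims=True)
        vnorm = np.sqrt((vz**2).sum(1))
        denom = vnorm * gnorm
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, a] = (vz @ gz) / denom
        out[denom == 0, a] = np.nan
    out[bad_vox] = np.nan
    return out


@dataclass
class ConnectivityMaps:
    """Group pulvino-cortical connectivity for one hemisphere.

    ``mean`` (n_voxels, n_areas) is the Fisher-z group average similarity,
    with one-sample t, two-tailed p and BH-FDR q per voxel and area.
    """

    mean: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    area_names: list
    n_subjects: int
    subject_maps: list = field(default_factory=list, repr=False)


def group_connectivity(subject_maps: list, area_names: list | None = None,
                       q: float = 0.05) -> ConnectivityMaps:
    """Fisher-z average and one-sample t-test of per-subject similarity maps.

    BH-FDR q-values are computed per area map over its voxels.
    """
    if len(subject_maps) < 2:
        raise ValueError("group connectivity needs at least 2 subjects")
    stack = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
    n_subj, n_vox, n_areas = stack.shape
    mean = np.full((n_vox, n_areas), np.nan)
    tval = np.full((n_vox, n_areas), np.nan)
    pval = np.full((n_vox, n_areas), np.nan)
    qval = np.full((n_vox, n_areas), np.nan)
    for a in range(n_areas):
        M = stack[:, :, a]
        ok = np.all(np.isfinite(M), axis=0)
        if not ok.any():
            continue
        tab = group_stats(M[:, ok], test="one_sample_t", correction="fdr_bh",
                          q=q, fisher=True)
        mean[ok, a] = tab["mean"].to_numpy()
        tval[ok, a] = tab["stat"].to_numpy()
        pval[ok, a] = tab["p"].to_numpy()
        qval[ok, a] = tab["q"].to_numpy()
    return ConnectivityMaps(mean=mean, t=tval, p=pval, q=qval,
                            area_names=list(area_names) if area_names else
                            [str(a) for a in range(n_areas)],
                            n_subjects=n_subj, subject_maps=list(subject_maps))


def split_half_reliability(subject_maps: list, iterations: int = 500,
                           seed: int | np.random.Generator = 0) -> dict:
    """Split-half reliability of the group maps.

    Per iteration, subjects are split into random halves (unbalanced when n
    is odd); per area, the spatial correlation between the two half-average
    maps is computed, and the mean over areas recorded.  Returns the mean,
    SD and per-iteration values.
    """
    n_subj = len(subject_maps)
    if n_subj < 4:
        raise ValueError("split-half reliability needs at least 4 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    Z = np.arctanh(np.clip(np.stack(subject_maps), -_ATANH_CLIP, _ATANH_CLIP))
    vals = np.empty(iterations)
    for it in range(iterations):
        perm = rng.permutation(n_subj)
        half1, half2 = perm[:n_subj // 2], perm[n_subj // 2:]
        m1 = np.tanh(Z[half1].mean(axis=0))
        m2 = np.tanh(Z[half2].mean(axis=0))
        rs = []
        for a in range(m1.shape[1]):
            ok = np.isfinite(m1[:, a]) & np.isfinite(m2[:, a])
            if ok.sum() > 2:
                rs.append(np.corrcoef(m1[ok, a], m2[ok, a])[0, 1])
        vals[it] = np.mean(rs)
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
            "iterations": vals}


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PulvinoCorticalModel:
    """Two-step pulvino-cortical coupling model.

    Parameters
    ----------
    datasets : list of SubjectDataset
        Pulvinar voxel time series per subject.
    area_set : AreaSet
        Cortical-area metadata and per-subject mean series.
    include_self : bool
        Keep the seed area's self-entry in the second-order correlation
        (excluded by default).
    within_hemisphere : bool
        Restrict profiles to ipsilateral correlations (default).
    preprocess : bool
        Apply the standard conditioning pipeline to voxel and area series
        before correlating.
    drop_seconds, smooth_fwhm_mm, q : float
        Preprocessing and thresholding parameters.
    """

    def __init__(self, datasets: list, area_set: AreaSet,
                 include_self: bool = False, within_hemisphere: bool = True,
                 preprocess: bool = True, drop_seconds: float = 21.6,
                 smooth_fwhm_mm: float = 4.0, q: float = 0.05):
        if not datasets:
            raise ValueError("need at least one subject dataset")
        ids = [d.subject_id for d in datasets]
        missing = [s for s in ids if s not in area_set.series]
        if missing:
            raise ValueError(f"area series missing for subjects: {missing}")
        self.datasets = list(datasets)
        self.area_set = area_set
        self.include_self = include_self
        self.within_hemisphere = within_hemisphere
        self.preprocess = preprocess
        self.drop_seconds = drop_seconds
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.q = q

    @classmethod
    def from_simulation(cls, config=None, **kwargs):
        """Build the model from a freshly generated synthetic resting
        dataset; returns (model, truth)."""
        from .synthdata import generate_resting_dataset
        datasets, area_set, truth = generate_resting_dataset(config)
        return cls(datasets, area_set, **kwargs), truth

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "PulvinoCorticalResults":
        datasets = self.datasets
        area_series = {d.subject_id: self.area_set.series[d.subject_id]
                       for d in datasets}
        if self.preprocess:
            datasets = [preprocess_dataset(d, drop_seconds=self.drop_seconds,
                                           smooth_fwhm_mm=self.smooth_fwhm_mm)
                        for d in datasets]
            area_series = {
                d.subject_id: preprocess_series(
                    self.area_set.series[d.subject_id], d.tr_seconds,
                    nuisance=d.nuisance, drop_seconds=self.drop_seconds)
                for d in self.datasets}

        hemis = self.area_set.hemispheres if self.within_hemisphere else ["all"]
        per_hemi = {}
        for hemi in hemis:
            if self.within_hemisphere:
                a_rows = self.area_set.rows_for_hemisphere(hemi)
                names = [self.area_set.names[i] for i in a_rows]
            else:
                a_rows = np.arange(self.area_set.n_rows)
                names = [f"{n}_{h}" for n, h in
                         zip(self.area_set.names, self.area_set.hemisphere)]
            profiles = {}
            vox_profs = {}
            for d in datasets:
                A = area_series[d.subject_id][a_rows]
                profiles[d.subject_id] = area_profile(A, names)
                v_sel = (d.hemisphere == hemi) if self.within_hemisphere \
                    else np.ones(d.n_voxels, dtype=bool)
                vox_profs[d.subject_id] = voxel_profiles(
                    d.voxel_series[v_sel], A)
            subject_maps = []
            for d in datasets:
                ref = pseudo_group_profile(profiles, d.subject_id) \
                    if len(datasets) > 1 else profiles[d.subject_id]
                subject_maps.append(profile_similarity_map(
                    vox_profs[d.subject_id], ref,
                    include_self=self.include_self))
            v_sel = (self.datasets[0].hemisphere == hemi) \
                if self.within_hemisphere \
                else np.ones(self.datasets[0].n_voxels, dtype=bool)
            per_hemi[hemi] = {
                "maps": group_connectivity(subject_maps, names, q=self.q),
                "area_names": names,
                "voxel_coords": self.datasets[0].voxel_coords_mm[v_sel],
                "profiles": profiles,
            }
        return PulvinoCorticalResults(model=self, per_hemisphere=per_hemi)


@dataclass
class PulvinoCorticalResults:
    """Fitted pulvino-cortical coupling: group maps per hemisphere plus
    network-structure summaries (computed lazily from the maps)."""

    model: PulvinoCorticalModel
    per_hemisphere: dict

    @property
    def hemispheres(self) -> list:
        return list(self.per_hemisphere.keys())

    @property
    def area_names(self) -> list:
        return self.per_hemisphere[self.hemispheres[0]]["area_names"]

    def connectivity(self, hemi: str) -> ConnectivityMaps:
        return self.per_hemisphere[hemi]["maps"]

    def map_similarity(self) -> np.ndarray:
        """Area-by-area correlation of group connectivity maps, computed per
        hemisphere and averaged across hemispheres."""
        from .netstruct import map_similarity
        group = {h: self.per_hemisphere[h]["maps"].mean
                 for h in self.hemispheres}
        return map_similarity(group, self.area_names)

    def mds(self, dims: int = 2) -> np.ndarray:
        from .netstruct import classical_mds, similarity_to_dissimilarity
        return classical_mds(
            similarity_to_dissimilarity(self.map_similarity()), dims)

    def clusters(self) -> np.ndarray:
        from .netstruct import spectral_clusters
        S = self.map_similarity().copy()
        np.fill_diagonal(S, 0.0)
        return spectral_clusters(S)

    def peaks(self, hemi: str, threshold_q: float | None = None) -> dict:
        """Peak mm coordinate of each area's group map in one hemisphere."""
        from .netstruct import peak_location
        block = self.per_hemisphere[hemi]
        maps = block["maps"]
        out = {}
        for a, name in enumerate(block["area_names"]):
            vals = maps.mean[:, a]
            mask = np.isfinite(vals)
            if threshold_q is not None:
                mask &= maps.q[:, a] < threshold_q
            out[name] = peak_location(vals, block["voxel_coords"], mask)
        return out

    def dice_matrix(self, q: float = 0.05) -> np.ndarray:
        """Pairwise Dice overlap of thresholded (BH-FDR q, positive)
        binarized group maps, averaged across hemispheres."""
        from .netstruct import dice_overlap
        mats = []
        for hemi in self.hemispheres:
            maps = self.per_hemisphere[hemi]["maps"]
            masks = (maps.q < q) & (maps.mean > 0)
            n = masks.shape[1]
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i, n):
                    D[i, j] = D[j, i] = dice_overlap(masks[:, i], masks[:, j])
            mats.append(D)
        return np.mean(mats, axis=0)

    def split_half(self, iterations: int = 500, seed=0) -> dict:
        out = {}
        for hemi in self.hemispheres:
            maps = self.per_hemisphere[hemi]["maps"]
            out[hemi] = split_half_reliability(maps.subject_maps,
                                               iterations, seed)
        return out

    def summary(self) -> str:
        """Human-readable overview of the fitted coupling structure."""
        labels = self.clusters()
        S = self.map_similarity()
        lines = [
            "Pulvino-cortical coupling results",
            "=" * 34,
            f"subjects: {len(self.model.datasets)}   "
            f"areas: {len(self.area_names)}   "
            f"hemispheres: {', '.join(map(str, self.hemispheres))}",
            f"clusters found: {labels.max() + 1}",
        ]
        for c in range(labels.max() + 1):
            members = [n for n, l in zip(self.area_names, labels) if l == c]
            lines.append(f"  cluster {c}: {', '.join(members)}")
        tri = S[np.triu_indices_from(S, k=1)]
        lines.append(f"map similarity: mean r = {tri.mean():.3f} "
                     f"(range {tri.min():.3f} to {tri.max():.3f})")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of group map values (hemisphere, area, voxel)."""
        rows = []
        for hemi in self.hemispheres:
            block = self.per_hemisphere[hemi]
            maps = block["maps"]
            for a, name in enumerate(block["area_names"]):
                for v in range(maps.mean.shape[0]):
                    rows.append({
                        "hemisphere": hemi, "area": name, "voxel": v,
                        "r": maps.mean[v, a], "t": maps.t[v, a],
                        "q": maps.q[v, a],
                    })
        return pd.DataFrame(rows)
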