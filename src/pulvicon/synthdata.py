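"""Synthetic multi-subject fMRI generators with planted ground truth.

Three experiment families are emulated, matching the study conditions of the
analyses in this package:

* **Resting state** — cortical-area signals organised into planted functional
  networks (an occipito-temporal-like and a fronto-parietal-like set), with
  pulvinar voxels formed as noisy topographic mixtures of nearby areas along
  a planted gradient, plus drift and motion-like nuisance structure.
* **Movie viewing** — a temporally autocorrelated stimulus feature course;
  regions with short (instantaneous) vs long (trailing moving-average)
  temporal receptive windows; an intact and a segment-scrambled condition
  sharing one permutation across subjects, two repetitions each.
* **Block designs** — HRF-convolved square-wave condition responses with
  planted effect sizes (laterality / attention and face / scene localizers).

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datatypes import (AreaSet, SimulationConfig, SimulationTruth,
                        SubjectDataset)

logger = logging.getLogger(__name__)

__all__ = [
    "generate_resting_dataset",
    "MovieConfig",
    "MovieDataset",
    "generate_stimulus",
    "movie_response",
    "scramble_stimulus",
    "SegmentPermutation",
    "generate_movie_dataset",
    "generate_block_design_dataset",
    "generate_laterality_dataset",
    "generate_localizer_dataset",
    "generate_dorsal_peaks",
]

_HEMI_SIGN = {"L": -1.0, "R": 1.0}


# ---------------------------------------------------------------------------
# Resting state
# ---------------------------------------------------------------------------

def _area_latents(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance area series hitting the planted network correlations.

    x_i = a*c + b1*g_net + b2*u_i + resid*e_i  with a global latent c
    (a^2 = between-network correlation), one flat latent g_net per network,
    and a graded component u_i: a Gaussian process over the ordered area
    index with correlation exp(-(i-j)^2 / (2*area_corr_length^2)).  The
    graded share is ``topography_corr`` (b2^2), so neighbouring areas on the
    planted gradient correlate at ~within_network_corr while distant pairs
    of the same network correlate at within_network_corr - topography_corr;
    this areal side of the planted topography is what makes connectivity
    fingerprints informative about position along the gradient
    (``area_corr_length=0`` or ``topography_corr=0`` collapse it to flat
    equicorrelation).
    """
    a = np.sqrt(cfg.between_network_corr)
    tc = cfg.topography_corr if cfg.area_corr_length > 0 else 0.0
    b1 = np.sqrt(cfg.within_network_corr - cfg.between_network_corr - tc)
    b2 = np.sqrt(tc)
    resid = np.sqrt(max(1.0 - a**2 - b1**2 - b2**2, 0.0))
    T = cfg.n_timepoints
    networks = cfg.networks
    c = rng.standard_normal(T)
    g = {net: rng.standard_normal(T) for net in networks}
    X = np.empty((cfg.n_areas, T))
    members = {net: [i for i, n in enumerate(cfg.area_names)
                     if cfg.network_assignment[n] == net]
               for net in networks}
    for net in networks:
        idx = members[net]
        m = len(idx)
        if b2 > 0:
            pos = np.arange(m)
            K = np.exp(-0.5 * ((pos[:, None] - pos[None, :])
                               / cfg.area_corr_length) ** 2)
            L = np.linalg.cholesky(K + 1e-10 * np.eye(m))
            U = L @ rng.standard_normal((m, T))
        else:
            U = np.zeros((m, T))
        for row, i in enumerate(idx):
            e = rng.standard_normal(T)
            X[i] = a * c + b1 * g[net] + b2 * U[row] + resid * e
    return X


def _grid_coords(cfg: SimulationConfig, hemi: str) -> tuple[np.ndarray, np.ndarray]:
    """Voxel lattice indices and mm coordinates for one hemisphere."""
    nx, ny, nz = cfg.grid_shape
    idx = np.array([(ix, iy, iz)
                    for ix in range(nx) for iy in range(ny) for iz in range(nz)])
    sx = _HEMI_SIGN[hemi]
    offset = np.array([6.0, -30.0, 2.0])   # pulvinar-like location
    mm = idx * cfg.grid_spacing_mm + offset
    mm[:, 0] = sx * mm[:, 0]
    return idx, mm


def _topography(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel mixing weights over areas, plus gradient and network labels.

    The z axis is split into one slab per network (first network ventral);
    within a slab the y index sets a gradient position that selects the
    preferred area within that network's ordered area list, with Gaussian
    falloff of width `topography_width` in area-index units (or a one-hot
    assignment).
    """
    nx, ny, nz = cfg.grid_shape
    idx, _ = _grid_coords(cfg, "R")
    networks = cfg.networks
    slab = np.minimum((idx[:, 2] * len(networks)) // nz, len(networks) - 1)
    gradient = idx[:, 1] / max(ny - 1, 1)
    n_vox = idx.shape[0]
    W = np.zeros((n_vox, cfg.n_areas))
    names = np.array(cfg.area_names)
    vox_net = np.empty(n_vox, dtype=object)
    for v in range(n_vox):
        net = networks[slab[v]]
        vox_net[v] = net
        members = np.flatnonzero(
            [cfg.network_assignment[a] == net for a in names])
        pref = gradient[v] * (len(members) - 1)
        if cfg.topography_kind == "one_hot":
            W[v, members[int(round(pref))]] = 1.0
        else:
            w = np.exp(-0.5 * ((np.arange(len(members)) - pref)
                               / cfg.topography_width) ** 2)
            W[v, members] = w / w.sum()
    return W, gradient, vox_net


def _planted_peaks(cfg: SimulationConfig, W: np.ndarray,
                   hemi: str) -> dict:
    """mm coordinate of each area's maximal topography weight (lexicographic
    smallest coordinate on ties)."""
    _, mm = _grid_coords(cfg, hemi)
    peaks = {}
    for j, name in enumerate(cfg.area_names):
        w = W[:, j]
        if w.max() <= 0:
            continue
        cand = np.flatnonzero(w >= w.max() - 1e-12)
        order = np.lexsort((mm[cand, 2], mm[cand, 1], mm[cand, 0]))
        peaks[(name, hemi)] = mm[cand[order[0]]].copy()
    return peaks


def _nuisance_signals(T: int, rng: np.random.Generator) -> np.ndarray:
    """Six motion-like smooth random walks plus ventricle- and white-matter-
    like global components, standardised; shape (T, 8)."""
    sig = gaussian_filter1d(np.cumsum(rng.standard_normal((8, T)), axis=1),
                            sigma=5.0, axis=1)
    sig = sig - sig.mean(axis=1, keepdims=True)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (sig / sd).T


def _area_centroids(cfg: SimulationConfig, hemi: str) -> np.ndarray:
    """Area centroids laid out along one arc per network so that cortical
    distance grows with planted gradient separation."""
    sx = _HEMI_SIGN[hemi]
    networks = cfg.networks
    cent = np.zeros((cfg.n_areas, 3))
    counters = {net: 0 for net in networks}
    for i, name in enumerate(cfg.area_names):
        net = cfg.network_assignment[name]
        k = networks.index(net)
        j = counters[net]
        counters[net] += 1
        cent[i] = (sx * 45.0, -90.0 + 6.0 * j, -10.0 + 55.0 * k)
    return cent


def generate_resting_dataset(config: SimulationConfig | None = None,
                             ) -> tuple[list, AreaSet, SimulationTruth]:
    """Generate a multi-subject resting-state dataset.

    Returns ``(datasets, area_set, truth)``: one :class:`SubjectDataset` per
    subject (voxels from both hemispheres concatenated, L first when
    bilateral), the cortical :class:`AreaSet` with per-subject mean series,
    and the planted :class:`SimulationTruth`.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    hemis = ["L", "R"] if cfg.bilateral else ["R"]
    W, gradient, vox_net = _topography(cfg)
    n_vox_h = W.shape[0]
    T = cfg.n_timepoints

    area_names, area_hemi, centroids = [], [], []
    peaks = {}
    for h in hemis:
        area_names += list(cfg.area_names)
        area_hemi += [h] * cfg.n_areas
        centroids.append(_area_centroids(cfg, h))
        peaks.update(_planted_peaks(cfg, W, h))
    centroids = np.vstack(centroids)
    diffs = centroids[:, None, :] - centroids[None, :, :]
    distances = np.sqrt((diffs**2).sum(-1))

    coords, hemi_labels = [], []
    for h in hemis:
        _, mm = _grid_coords(cfg, h)
        coords.append(mm)
        hemi_labels += [h] * n_vox_h
    coords = np.vstack(coords)
    hemi_labels = np.array(hemi_labels)

    tt = np.linspace(-1.0, 1.0, T)
    drift_basis = np.stack([tt, (3 * tt**2 - 1) / 2.0])

    datasets = []
    series = {}
    for s in range(cfg.n_subjects):
        sid = f"sub-{s:02d}"
        area_blocks, voxel_blocks = [], []
        nuis = _nuisance_signals(T, rng)
        for h in hemis:
            A = _area_latents(cfg, rng)
            area_blocks.append(A)
            vox = W @ A
            vox += cfg.noise_sd * rng.standard_normal((n_vox_h, T))
            if cfg.drift_amplitude > 0:
                vox += cfg.drift_amplitude * (
                    rng.standard_normal((n_vox_h, 2)) @ drift_basis)
            if cfg.nuisance_amplitude > 0:
                loads = (cfg.nuisance_amplitude / np.sqrt(nuis.shape[1])
                         * rng.standard_normal((n_vox_h, nuis.shape[1])))
                vox += loads @ nuis.T
            voxel_blocks.append(vox)
        series[sid] = np.vstack(area_blocks)
        datasets.append(SubjectDataset(
            subject_id=sid,
            voxel_series=np.vstack(voxel_blocks),
            tr_seconds=cfg.tr_seconds,
            voxel_coords_mm=coords,
            hemisphere=hemi_labels,
            nuisance=nuis,
        ))

    area_set = AreaSet(
        names=area_names, hemisphere=np.array(area_hemi), series=series,
        centroids_mm=centroids, distances_mm=distances,
        networks=np.array([cfg.network_assignment[a] for a in area_names]),
    )
    truth = SimulationTruth(
        network_assignment=dict(cfg.network_assignment),
        voxel_gradient={h: gradient.copy() for h in hemis},
        voxel_network={h: vox_net.copy() for h in hemis},
        planted_peak=peaks,
    )
    return datasets, area_set, truth


# ---------------------------------------------------------------------------
# Movie viewing
# ---------------------------------------------------------------------------

@dataclass
class MovieConfig:
    """Study conditions of the movie-viewing (timescale localizer) simulation:
    11 subjects, a 5 min 45 s clip at TR 1.5 s presented twice per condition,
    scrambling segments of 0.5-1.6 s."""

    n_subjects: int = 11
    tr_seconds: float = 1.5
    n_timepoints: int = 230
    n_repetitions: int = 2
    n_voxels_per_region: int = 20
    stimulus_dt_seconds: float = 0.25
    stimulus_autocorr_seconds: float = 2.5
    segment_min_seconds: float = 0.5
    segment_max_seconds: float = 1.6
    noise_sd: float = 0.8
    trw_seconds: dict = field(default_factory=lambda: {"short": 0.0, "long": 21.0})
    seed: int = 0


@dataclass
class SegmentPermutation:
    """Record of a segment scrambling: segment start offsets (samples) into
    the original course, their lengths, and the presented order."""

    boundaries: np.ndarray   # segment start indices in the original course
    lengths: np.ndarray
    order: np.ndarray        # permutation applied to the segments


def generate_stimulus(n_samples: int, dt_seconds: float,
                      autocorr_seconds: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Temporally autocorrelated stimulus feature course (unit variance).

    Gaussian-filtered white noise; the autocorrelation scale stands in for
    the moment-to-moment drift of low-level visual statistics of a movie.
    """
    raw = rng.standard_normal(n_samples)
    stim = gaussian_filter1d(raw, sigma=autocorr_seconds / dt_seconds,
                             mode="wrap")
    stim = stim - stim.mean()
    sd = stim.std()
    return stim / sd if sd > 0 else stim


def movie_response(stimulus: np.ndarray, window_samples: int) -> np.ndarray:
    """Noiseless regional response to a stimulus course.

    ``window_samples == 1`` is the instantaneous (short temporal receptive
    window) response; larger windows give the trailing moving average over
    the preceding `window_samples` samples (edge-truncated at the start).
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if window_samples < 1:
        raise ValueError("window must be at least one sample")
    if window_samples > stimulus.size:
        raise ValueError("integration window longer than the stimulus")
    if window_samples == 1:
        return stimulus.copy()
    csum = np.concatenate([[0.0], np.cumsum(stimulus)])
    n = np.arange(stimulus.size)
    lo = np.maximum(n - window_samples + 1, 0)
    return (csum[n + 1] - csum[lo]) / (n + 1 - lo)


def scramble_stimulus(stimulus: np.ndarray, dt_seconds: float,
                      segment_min_seconds: float = 0.5,
                      segment_max_seconds: float = 1.6,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None,
                      ) -> tuple[np.ndarray, SegmentPermutation]:
    """Break the course into contiguous segments of 0.5-1.6 s (final
    remainder kept) and reorder them with a recorded permutation."""
    if segment_min_seconds <= 0 or segment_max_seconds <= 0:
        raise ValueError("segment bounds must be positive")
    if segment_max_seconds < segment_min_seconds:
        raise ValueError("segment_max must be >= segment_min")
    stimulus = np.asarray(stimulus, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    smin = max(1, int(round(segment_min_seconds / dt_seconds)))
    smax = max(smin, int(segment_max_seconds / dt_seconds))
    bounds, lengths = [], []
    pos = 0
    n = stimulus.size
    while pos < n:
        seg = int(rng.integers(smin, smax + 1))
        seg = min(seg, n - pos)          # final remainder segment kept
        bounds.append(pos)
        lengths.append(seg)
        pos += seg
    bounds = np.array(bounds)
    lengths = np.array(lengths)
    order = rng.permutation(len(bounds))
    out = np.concatenate([stimulus[bounds[k]:bounds[k] + lengths[k]]
                          for k in order])
    return out, SegmentPermutation(boundaries=bounds, lengths=lengths,
                                   order=order)


@dataclass
class MovieDataset:
    """Simulated movie-viewing responses for both conditions.

    ``responses[condition][region]`` has shape
    (n_subjects, n_repetitions, n_voxels, n_timepoints);
    ``noiseless[condition][region]`` is the shared stimulus-locked signal.
    """

    config: MovieConfig
    stimulus_intact: np.ndarray
    stimulus_scrambled: np.ndarray
    permutation: SegmentPermutation
    responses: dict
    noiseless: dict
    truth: SimulationTruth


def generate_movie_dataset(config: MovieConfig | None = None,
                           trw_spec: dict | None = None) -> MovieDataset:
    """Simulate intact and segment-scrambled movie responses.

    The stimulus course lives on a fine grid (`stimulus_dt_seconds`); each
    region's noiseless response is a fixed function of the presented course
    (pointwise for short-window regions, trailing moving average over the
    stated window for long-window regions), box-averaged into TR bins and
    shared across subjects; independent per-subject/repetition noise of SD
    ``noise_sd`` is added.  All subjects share one segment permutation.
    Scrambling a long window over many short incoherent segments collapses
    the shared signal variance, which is what makes long-window regions lose
    inter-subject consistency in the scrambled condition.
    """
    cfg = config or MovieConfig()
    trw = dict(trw_spec) if trw_spec is not None else dict(cfg.trw_seconds)
    dt = cfg.stimulus_dt_seconds
    per_tr = int(round(cfg.tr_seconds / dt))
    if abs(per_tr * dt - cfg.tr_seconds) > 1e-9 or per_tr < 1:
        raise ValueError("tr_seconds must be an integer multiple of the "
                         "stimulus dt")
    n_fine = cfg.n_timepoints * per_tr
    rng = np.random.default_rng(cfg.seed)
    stim = generate_stimulus(n_fine, dt, cfg.stimulus_autocorr_seconds, rng)
    scrambled, perm = scramble_stimulus(
        stim, dt, cfg.segment_min_seconds, cfg.segment_max_seconds, rng=rng)

    for region, w in trw.items():
        if w > 0 and w < cfg.tr_seconds:
            raise ValueError(
                f"long-window region {region!r} has window {w} s < TR")
        if w > cfg.n_timepoints * cfg.tr_seconds:
            raise ValueError(f"window for {region!r} longer than the run")

    noiseless = {"intact": {}, "scrambled": {}}
    responses = {"intact": {}, "scrambled": {}}
    courses = {"intact": stim, "scrambled": scrambled}
    sample_at = np.arange(cfg.n_timepoints) * per_tr + per_tr - 1
    for cond in ("intact", "scrambled"):
        for region, w in trw.items():
            win = max(1, int(round(w / dt)))
            fine = movie_response(courses[cond], win)
            # point-sample at TR resolution: an instantaneous region must
            # not integrate across segment boundaries via the readout
            noiseless[cond][region] = fine[sample_at]
    for cond in ("intact", "scrambled"):
        for region in trw:
            sig = noiseless[cond][region]
            noise = cfg.noise_sd * rng.standard_normal(
                (cfg.n_subjects, cfg.n_repetitions,
                 cfg.n_voxels_per_region, cfg.n_timepoints))
            responses[cond][region] = sig[None, None, None, :] + noise

    truth = SimulationTruth(trw_label={
        r: ("long" if w > 0 else "short") for r, w in trw.items()})
    return MovieDataset(config=cfg, stimulus_intact=stim,
                        stimulus_scrambled=scrambled, permutation=perm,
                        responses=responses, noiseless=noiseless, truth=truth)


# ---------------------------------------------------------------------------
# Block designs
# ---------------------------------------------------------------------------

def generate_block_design_dataset(config: SimulationConfig,
                                  block_table: pd.DataFrame,
                                  planted_betas: dict,
                                  hrf_kind: str = "double_gamma",
                                  ) -> tuple[list, pd.DataFrame, SimulationTruth]:
    """Simulate block-design runs with planted per-voxel effect sizes.

    ``planted_betas`` maps condition -> per-voxel amplitude array (length
    n_voxels of the configured grid, both hemispheres when bilateral).  The
    voxel signal is planted_betas x HRF-convolved square waves + drift +
    white noise.  Returns (datasets, block_table, truth).
    """
    from .taskglm import condition_regressors

    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    hemis = ["L", "R"] if cfg.bilateral else ["R"]
    coords, hemi_labels = [], []
    for h in hemis:
        _, mm = _grid_coords(cfg, h)
        coords.append(mm)
        hemi_labels += [mm.shape[0] * [h]][0]
    coords = np.vstack(coords)
    hemi_labels = np.array(hemi_labels)
    n_vox = coords.shape[0]
    T = cfg.n_timepoints

    regs = condition_regressors(block_table, cfg.tr_seconds, T,
                                hrf_kind=hrf_kind)
    B = np.zeros((n_vox, len(regs.columns)))
    for j, cond in enumerate(regs.columns):
        if cond in planted_betas:
            beta = np.asarray(planted_betas[cond], dtype=float)
            if beta.shape != (n_vox,):
                raise ValueError(
                    f"planted beta for {cond!r} has shape {beta.shape}, "
                    f"expected ({n_vox},)")
            B[:, j] = beta
    signal = B @ regs.to_numpy().T

    tt = np.linspace(-1.0, 1.0, T)
    datasets = []
    for s in range(cfg.n_subjects):
        vox = signal.copy()
        if cfg.drift_amplitude > 0:
            vox += cfg.drift_amplitude * rng.standard_normal((n_vox, 1)) * tt
        if cfg.noise_sd > 0:
            vox += cfg.noise_sd * rng.standard_normal((n_vox, T))
        nuis = _nuisance_signals(T, rng)[:, :6]
        datasets.append(SubjectDataset(
            subject_id=f"sub-{s:02d}", voxel_series=vox,
            tr_seconds=cfg.tr_seconds, voxel_coords_mm=coords,
            hemisphere=hemi_labels, nuisance=nuis))
    truth = SimulationTruth(planted_betas={
        c: np.asarray(v, dtype=float) for c, v in planted_betas.items()})
    return datasets, block_table, truth


def _block_table(conditions: list, block_seconds: float = 16.0,
                 rest_seconds: float = 16.0, n_cycles: int = 4) -> pd.DataFrame:
    """Alternating 16 s condition / 16 s fixation blocks, `n_cycles` passes
    through the condition list."""
    rows = []
    t = rest_seconds
    for _ in range(n_cycles):
        for cond in conditions:
            rows.append({"onset": t, "duration": block_seconds,
                         "condition": cond})
            t += block_seconds + rest_seconds
    return pd.DataFrame(rows)


def _compartment_masks(cfg: SimulationConfig) -> dict:
    """Boolean masks over the full (bilateral) voxel axis per network slab."""
    _, gradient, vox_net = _topography(cfg)
    n_rep = 2 if cfg.bilateral else 1
    full_net = np.concatenate([vox_net] * n_rep)
    return {net: full_net == net for net in cfg.networks}


def generate_laterality_dataset(config: SimulationConfig | None = None,
                                ) -> tuple[list, pd.DataFrame, SimulationTruth]:
    """Laterality / attentional-modulation experiment: 16 s blocks at TR 2 s,
    5 subjects.  Ventral (occipito-temporal compartment) voxels get strong
    contralateral tuning; dorsal voxels get strong attentional modulation."""
    cfg = replace(config or SimulationConfig(),
                  n_subjects=5, tr_seconds=2.0, n_timepoints=240,
                  noise_sd=0.5)
    table = _block_table(["stim_contra", "stim_ipsi", "attend_contra"])
    comp = _compartment_masks(cfg)
    ventral = comp[cfg.networks[0]]
    dorsal = ~ventral
    n_vox = ventral.size
    betas = {c: np.zeros(n_vox) for c in
             ("stim_contra", "stim_ipsi", "attend_contra")}
    betas["stim_contra"][ventral] = 1.0
    betas["stim_ipsi"][ventral] = 0.2
    betas["attend_contra"][ventral] = 1.1
    betas["stim_contra"][dorsal] = 0.3
    betas["stim_ipsi"][dorsal] = 0.25
    betas["attend_contra"][dorsal] = 0.9
    datasets, table, truth = generate_block_design_dataset(cfg, table, betas)
    truth.voxel_network = {"all": np.where(ventral, "ventral", "dorsal")}
    return datasets, table, truth


def generate_localizer_dataset(config: SimulationConfig | None = None,
                               ) -> tuple[list, pd.DataFrame, SimulationTruth]:
    """Face / scene category localizer: 16 subjects, with a planted
    face-selective cluster in the posterior-medial ventral compartment."""
    cfg = replace(config or SimulationConfig(),
                  n_subjects=16, tr_seconds=2.0, n_timepoints=240,
                  noise_sd=0.6)
    table = _block_table(["face", "scene"])
    hemis = ["L", "R"] if cfg.bilateral else ["R"]
    idx_blocks = []
    for _h in hemis:
        idx, _ = _grid_coords(cfg, "R")
        idx_blocks.append(idx)
    idx = np.vstack(idx_blocks)
    nx, ny, nz = cfg.grid_shape
    posterior_medial_ventral = ((idx[:, 2] < nz // 2)
                                & (idx[:, 1] < ny // 2)
                                & (idx[:, 0] < (nx + 1) // 2))
    n_vox = idx.shape[0]
    betas = {"face": np.full(n_vox, 0.4), "scene": np.full(n_vox, 0.4)}
    betas["face"][posterior_medial_ventral] = 1.2
    betas["scene"][posterior_medial_ventral] = 0.2
    datasets, table, truth = generate_block_design_dataset(cfg, table, betas)
    truth.voxel_network = {"all": np.where(posterior_medial_ventral,
                                           "face_cluster", "background")}
    return datasets, table, truth


# ---------------------------------------------------------------------------
# Dorsal peak configuration
# ---------------------------------------------------------------------------

def generate_dorsal_peaks(n_groups: int = 3, areas_per_group: int = 5,
                          spread_mm: float = 1.5,
                          seed: int = 0) -> tuple[pd.DataFrame, SimulationTruth]:
    """Connectivity-peak coordinates with planted groupings.

    Emulates the finer structure of dorsal-pulvinar coupling: distinct
    attention-like, tool-like, and default-mode-like peak clusters, with
    within-group spread small relative to between-group separation.
    """
    group_names = ["attention", "tool", "default_mode"][:n_groups]
    while len(group_names) < n_groups:
        group_names.append(f"group{len(group_names)}")
    # comparably separated group centres (16-18 mm apart, spread 1.5 mm)
    centers = np.array([[12.0, -28.0, 12.0],
                        [2.0, -20.0, 2.0],
                        [10.0, -12.0, 16.0]])
    extra = n_groups - centers.shape[0]
    if extra > 0:
        more = np.array([[2.0 + 14.0 * k, -34.0 - 10.0 * k, 20.0 + 8.0 * k]
                         for k in range(extra)])
        centers = np.vstack([centers, more])
    rng = np.random.default_rng(seed)
    rows = []
    labels = {}
    for g, gname in enumerate(group_names):
        for a in range(areas_per_group):
            name = f"{gname}_{a}"
            xyz = centers[g] + spread_mm * rng.standard_normal(3)
            rows.append({"area": name, "group": gname,
                         "x": xyz[0], "y": xyz[1], "z": xyz[2]})
            labels[name] = gname
    table = pd.DataFrame(rows)
    return table, SimulationTruth(network_assignment=labels)
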