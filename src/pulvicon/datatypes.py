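"""Core data containers shared across the analysis modules.

Coordinates are millimetres in the volume's affine frame; voxel indices are
0-based; the left hemisphere occupies negative x (MNI convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectDataset:
    """One subject's masked voxel time series.

    Parameters
    ----------
    subject_id : str
        Label identifying the subject.
    voxel_series : ndarray, shape (n_voxels, n_timepoints)
        BOLD signal per voxel (arbitrary units).
    tr_seconds : float
        Repetition time of the acquisition.
    voxel_coords_mm : ndarray, shape (n_voxels, 3)
        World coordinates of each voxel centre.
    hemisphere : ndarray of {'L', 'R'}, shape (n_voxels,)
        Hemisphere membership per voxel (left = negative x).
    mask_id : str
        Name of the mask the voxels were drawn from.
    nuisance : ndarray, shape (n_timepoints, k), optional
        Nuisance regressors (motion estimates, ventricle / white-matter
        signals) recorded for this subject.
    """

    subject_id: str
    voxel_series: np.ndarray
    tr_seconds: float
    voxel_coords_mm: np.ndarray
    hemisphere: np.ndarray
    mask_id: str = "pulvinar"
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxel_series = np.asarray(self.voxel_series, dtype=float)
        self.voxel_coords_mm = np.asarray(self.voxel_coords_mm, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.voxel_series.ndim != 2:
            raise ValueError("voxel_series must be 2-D (voxels x time)")
        n_vox = self.voxel_series.shape[0]
        if self.voxel_coords_mm.shape != (n_vox, 3):
            raise ValueError(
                f"voxel_coords_mm shape {self.voxel_coords_mm.shape} does not "
                f"match {n_vox} voxels"
            )
        if self.hemisphere.shape != (n_vox,):
            raise ValueError("hemisphere must have one entry per voxel")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.voxel_series)):
            raise ValueError("voxel_series contains non-finite samples")
        uniq = np.unique(self.voxel_coords_mm, axis=0)
        if uniq.shape[0] != n_vox:
            raise ValueError("voxel coordinates must be unique per voxel")

    @property
    def n_voxels(self) -> int:
        return self.voxel_series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.voxel_series.shape[1]


@dataclass
class AreaSet:
    """Cortical-area metadata and mean time series.

    Rows index (area name, hemisphere) pairs; an area present in both
    hemispheres contributes two rows with the same ``name``.

    Attributes
    ----------
    names : list of str
        Area name per row (e.g. V1, FFA, IPS3).
    hemisphere : ndarray of {'L', 'R'}
        Hemisphere per row.
    series : dict subject_id -> ndarray (n_rows, n_timepoints)
        Mean time series of each area for each subject.
    centroids_mm : ndarray, shape (n_rows, 3)
        Surface-centroid coordinate per area.
    distances_mm : ndarray, shape (n_rows, n_rows)
        Pairwise cortical distances (symmetric, zero diagonal).
    networks : ndarray of str, optional
        Network label per row (used by the synthetic generator's truth).
    parcellation : str
        Tag identifying the parcellation ({'functional-39', 'hcp-180', ...}).
    """

    names: list
    hemisphere: np.ndarray
    series: dict
    centroids_mm: np.ndarray
    distances_mm: np.ndarray
    networks: np.ndarray | None = None
    parcellation: str = "functional-39"

    def __post_init__(self) -> None:
        self.hemisphere = np.asarray(self.hemisphere)
        self.centroids_mm = np.asarray(self.centroids_mm, dtype=float)
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        n = len(self.names)
        if self.hemisphere.shape != (n,):
            raise ValueError("hemisphere must have one entry per area row")
        if self.centroids_mm.shape != (n, 3):
            raise ValueError("centroids_mm must be (n_rows, 3)")
        if self.distances_mm.shape != (n, n):
            raise ValueError("distances_mm must be square over area rows")
        if not np.allclose(self.distances_mm, self.distances_mm.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.distances_mm), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        for sid, mat in self.series.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape[0] != n:
                raise ValueError(
                    f"series for subject {sid!r} has {mat.shape[0]} rows, "
                    f"expected {n}"
                )
            self.series[sid] = mat

    @property
    def n_rows(self) -> int:
        return len(self.names)

    @property
    def subject_ids(self) -> list:
        return list(self.series.keys())

    def rows_for_hemisphere(self, hemi: str) -> np.ndarray:
        """Indices of rows belonging to one hemisphere."""
        return np.flatnonzero(self.hemisphere == hemi)

    def subset(self, area_names: list) -> "AreaSet":
        """Restrict to a subset of area names (both hemispheres), e.g. to
        analyse a reduced parcellation."""
        keep = np.array([n in set(area_names) for n in self.names])
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            raise ValueError("subset selects no areas")
        return AreaSet(
            names=[self.names[i] for i in idx],
            hemisphere=self.hemisphere[idx],
            series={s: m[idx] for s, m in self.series.items()},
            centroids_mm=self.centroids_mm[idx],
            distances_mm=self.distances_mm[np.ix_(idx, idx)],
            networks=None if self.networks is None else self.networks[idx],
            parcellation="custom",
        )

    @property
    def hemispheres(self) -> list:
        out = []
        for h in self.hemisphere:
            if h not in out:
                out.append(h)
        return out


# ---------------------------------------------------------------------------
# Simulation configuration and ground truth
# ---------------------------------------------------------------------------

#: 39 cortical areas of the default parcellation.  The first block covers
#: occipital and temporal cortex (retinotopic maps plus category-selective
#: domains); the second covers parietal and frontal cortex plus default-mode
#: and tool-network areas.
DEFAULT_AREAS_OCCIPITOTEMPORAL = [
    "V1", "V2", "V3", "V3A", "V3B", "hV4", "VO1", "VO2", "PHC1", "PHC2",
    "LO1", "LO2", "TO1", "TO2", "OFA", "FFA", "AT", "pSTS", "EBA", "FBA",
    "PPA", "TOS", "LOC",
]
DEFAULT_AREAS_FRONTOPARIETAL = [
    "IPS0", "IPS1", "IPS2", "IPS3", "IPS4", "IPS5", "SPL1", "IFS", "FEF",
    "RSC", "PreC", "IPL", "latTemp", "antPPC", "latPPC", "medPPC",
]
DEFAULT_AREA_NAMES = DEFAULT_AREAS_OCCIPITOTEMPORAL + DEFAULT_AREAS_FRONTOPARIETAL

DEFAULT_NETWORKS = {name: "occipitotemporal" for name in DEFAULT_AREAS_OCCIPITOTEMPORAL}
DEFAULT_NETWORKS.update({name: "frontoparietal" for name in DEFAULT_AREAS_FRONTOPARIETAL})


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-subject generator.

    The defaults emulate the study conditions of the resting-state coupling
    analysis: 13 subjects, 39 cortical areas in two functional networks,
    TR 1.8 s, ten-minute runs, and a pulvinar-like voxel block per hemisphere
    whose voxels mix nearby areas along a topographic gradient.
    """

    n_subjects: int = 13
    area_names: list = field(default_factory=lambda: list(DEFAULT_AREA_NAMES))
    network_assignment: dict = field(default_factory=lambda: dict(DEFAULT_NETWORKS))
    bilateral: bool = True
    grid_shape: tuple = (4, 6, 8)       # per-hemisphere voxel lattice (x, y, z)
    grid_spacing_mm: float = 2.0
    topography_kind: str = "gradient"   # {'gradient', 'one_hot'}
    topography_width: float = 1.5       # Gaussian width in area-index units
    tr_seconds: float = 1.8
    n_timepoints: int = 312             # ~9.4 min at TR 1.8 s
    noise_sd: float = 0.8
    within_network_corr: float = 0.45
    between_network_corr: float = 0.10
    area_corr_length: float = 3.0       # GP length of the areal topography,
                                        # in area-index units (0 = flat)
    topography_corr: float = 0.30       # graded share of the within-network
                                        # correlation
    drift_amplitude: float = 0.5
    nuisance_amplitude: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        w, b = self.within_network_corr, self.between_network_corr
        if not (0.0 <= b <= w <= 1.0):
            raise ValueError(
                "implied latent covariance is not positive semi-definite: "
                f"need 0 <= between_network_corr ({b}) <= "
                f"within_network_corr ({w}) <= 1"
            )
        if not (0.0 <= self.topography_corr <= w - b):
            raise ValueError(
                "implied latent covariance is not positive semi-definite: "
                f"need 0 <= topography_corr ({self.topography_corr}) <= "
                f"within_network_corr - between_network_corr ({w - b})"
            )
        if self.n_subjects < 1 or self.n_timepoints < 8:
            raise ValueError("need at least 1 subject and 8 timepoints")
        missing = [a for a in self.area_names if a not in self.network_assignment]
        if missing:
            raise ValueError(f"areas without a network assignment: {missing}")
        if self.topography_kind not in ("gradient", "one_hot"):
            raise ValueError(f"unknown topography_kind {self.topography_kind!r}")

    @property
    def n_areas(self) -> int:
        return len(self.area_names)

    @property
    def networks(self) -> list:
        seen = []
        for a in self.area_names:
            lab = self.network_assignment[a]
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class SimulationTruth:
    """Planted parameters recorded by the generators for recovery tests."""

    network_assignment: dict | None = None          # area name -> network label
    voxel_gradient: dict | None = None              # subject-invariant, per hemi:
                                                    # hemi -> ndarray (n_voxels,)
    voxel_network: dict | None = None               # hemi -> array of network labels
    planted_peak: dict | None = None                # (area, hemi) -> 3-vector (mm)
    trw_label: dict | None = None                   # region -> {'short', 'long'}
    planted_betas: dict | None = None               # condition -> ndarray (n_voxels,)
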