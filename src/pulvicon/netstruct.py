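"""Network-level structure of pulvino-cortical connectivity maps.

Given the per-area voxel maps, this module computes the area-by-area map
similarity, embeds its dissimilarity by classical (Torgerson) MDS, tests
subject-vs-group configuration agreement with Procrustes permutation tests,
partitions the similarity graph by Newman's spectral modularity (leading
eigenvector, recursive bisection with automatic stopping), and relates map
overlap (Dice), peak geometry and cortical distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes

logger = logging.getLogger(__name__)

__all__ = [
    "map_similarity",
    "similarity_to_dissimilarity",
    "classical_mds",
    "spectral_clusters",
    "procrustes_fit",
    "permutation_test_mds",
    "PermutationTestResult",
    "dice_overlap",
    "peak_location",
    "bilateral_average",
    "distance_relationships",
    "fisher_z_difference",
    "plot_mds",
    "peak_cluster",
]


# ---------------------------------------------------------------------------
# Map similarity and MDS
# ---------------------------------------------------------------------------

def map_similarity(group_maps: dict | np.ndarray,
                   area_names: list | None = None) -> np.ndarray:
    """Area-by-area Pearson correlation of vectorized connectivity maps.

    `group_maps` is either a single (n_voxels, n_areas) array or a dict
    hemisphere -> array; with multiple hemispheres the per-hemisphere
    similarity matrices are averaged.
    """
    if isinstance(group_maps, dict):
        mats = [_one_similarity(np.asarray(m, float), area_names)
                for m in group_maps.values()]
        return np.mean(mats, axis=0)
    return _one_similarity(np.asarray(group_maps, float), area_names)


def _one_similarity(maps: np.ndarray, area_names) -> np.ndarray:
    ok = np.all(np.isfinite(maps), axis=1)
    M = maps[ok]
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        label = [area_names[i] for i in bad] if area_names else bad.tolist()
        raise ValueError(f"constant connectivity map for area(s): {label}")
    return np.corrcoef(M.T)


def similarity_to_dissimilarity(similarity: np.ndarray) -> np.ndarray:
    """Euclidean distances between rows of the similarity matrix (the
    dissimilarity input for classical MDS)."""
    S = np.asarray(similarity, dtype=float)
    d2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(-1)
    return np.sqrt(np.maximum(d2, 0.0))


def classical_mds(dissimilarity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared dissimilarities and projects on the top
    `dims` eigenvectors scaled by the square root of their eigenvalues;
    negative eigenvalues are truncated at zero (logged).  Axes are ordered
    by decreasing eigenvalue with a deterministic sign convention.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("dissimilarity must have zero diagonal")
    if np.any(D < 0):
        raise ValueError("dissimilarity must be nonnegative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1][:dims]
    lam = evals[order]
    if np.any(lam < -1e-10 * max(abs(evals).max(), 1.0)):
        logger.info("classical_mds: truncating negative eigenvalues %s",
                    lam[lam < 0])
    lam = np.maximum(lam, 0.0)
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):  # deterministic axis signs
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


# ---------------------------------------------------------------------------
# Newman spectral modularity
# ---------------------------------------------------------------------------

def spectral_clusters(weights: np.ndarray, zero_negative: bool = True,
                      ) -> np.ndarray:
    """Newman leading-eigenvector modularity clustering with automatic
    stopping.

    Recursively bisects along the leading eigenvector of the (generalized)
    modularity matrix, refines each bisection with the Kernighan-Lin-style
    fine-tuning pass of Newman's original algorithm, and leaves a group
    intact when the eigenvector signs are uniform or when the split's
    modularity contribution is not positive, so the number of clusters is
    determined by the data.  Negative edge weights are zeroed by default
    (``zero_negative=False`` keeps them, a signed variant).  Returns integer
    labels 0..k-1 in first-appearance order.
    """
    W = np.asarray(weights, dtype=float).copy()
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    np.fill_diagonal(W, 0.0)
    if zero_negative:
        W[W < 0] = 0.0
    if W.shape[0] == 0 or not np.any(W != 0):
        raise ValueError("empty graph: no nonzero edge weights")
    k = W.sum(axis=1)
    two_m = k.sum()
    B = W - np.outer(k, k) / two_m
    n = W.shape[0]
    labels = np.zeros(n, dtype=int)
    stack = [np.arange(n)]
    next_label = 1
    while stack:
        g = stack.pop()
        if g.size < 2:
            continue
        Bg = B[np.ix_(g, g)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        evals, evecs = np.linalg.eigh((Bg + Bg.T) / 2.0)
        v = evecs[:, -1]
        s = np.where(v >= 0, 1.0, -1.0)
        if np.all(s == s[0]):          # sign-uniform: indivisible
            continue
        s = _fine_tune(Bg, s)
        if np.all(s == s[0]):
            continue
        dq = s @ Bg @ s / (4.0 * two_m)
        if dq <= 1e-12:
            continue
        g1, g2 = g[s > 0], g[s < 0]
        labels[g2] = next_label
        next_label += 1
        stack.append(g1)
        stack.append(g2)
    # relabel in first-appearance order
    _, canon = np.unique(labels, return_index=True)
    remap = {labels[i]: r for r, i in enumerate(sorted(canon))}
    return np.array([remap[l] for l in labels])


def _fine_tune(Bg: np.ndarray, s: np.ndarray, max_rounds: int = 30,
               ) -> np.ndarray:
    """Kernighan-Lin-style refinement of a bisection.

    Repeatedly passes over all vertices, moving each (once per pass, in order
    of modularity gain) to the other side and keeping the best intermediate
    configuration, until a pass no longer improves s' Bg s.
    """
    s = s.copy()
    best_q = s @ Bg @ s
    n = s.size
    for _ in range(max_rounds):
        moved = np.zeros(n, dtype=bool)
        s_pass = s.copy()
        trail = []
        q = best_q
        for _step in range(n):
            # gain of flipping vertex i: -4 s_i (Bg s)_i + 4 Bg_ii
            bs = Bg @ s_pass
            gains = -4.0 * s_pass * bs + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            s_pass[i] = -s_pass[i]
            moved[i] = True
            q = q + gains[i]
            trail.append((q, s_pass.copy()))
        pass_best_q, pass_best_s = max(trail, key=lambda t: t[0])
        if pass_best_q > best_q + 1e-12:
            best_q, s = pass_best_q, pass_best_s
        else:
            break
    return s


# ---------------------------------------------------------------------------
# Procrustes and permutation tests
# ---------------------------------------------------------------------------

def procrustes_fit(source: np.ndarray, target: np.ndarray,
                   ) -> tuple[np.ndarray, float]:
    """Full Procrustes alignment of `source` onto `target`.

    Optimal translation, rotation/reflection and isotropic scaling; returns
    the aligned source (in the standardized target frame) and the SSE
    normalised by the target configuration's total variance (scipy's
    disparity).
    """
    A = np.asarray(source, dtype=float)
    Bt = np.asarray(target, dtype=float)
    if A.shape != Bt.shape:
        raise ValueError("source and target must have matching shapes")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 points")
    _, aligned, sse = _scipy_procrustes(Bt, A)
    return aligned, float(sse)


@dataclass
class PermutationTestResult:
    """Observed Procrustes SSE against a label-permutation null."""

    observed_sse: float
    null_sse: np.ndarray
    mode: str

    @property
    def percentile(self) -> float:
        """Fraction of null SSEs at or below the observed (rank p-value
        (1 + #{null <= obs}) / (n + 1); small = better-than-chance fit)."""
        n = self.null_sse.size
        return (1.0 + np.sum(self.null_sse <= self.observed_sse)) / (n + 1.0)


def permutation_test_mds(subject_coords: np.ndarray,
                         group_coords: np.ndarray,
                         n_perm: int = 1000, mode: str = "global",
                         clusters: np.ndarray | None = None,
                         seed: int | np.random.Generator = 0,
                         ) -> PermutationTestResult:
    """Procrustes goodness-of-fit permutation test for MDS configurations.

    The observed SSE aligns the subject's 2-D configuration to the (pseudo-)
    group configuration.  The null scrambles the area labels of the subject
    configuration — across all areas (``global``) or only within the
    provided clusters (``within_cluster``) — and realigns.
    """
    S = np.asarray(subject_coords, dtype=float)
    G = np.asarray(group_coords, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    _, observed = procrustes_fit(S, G)
    n = S.shape[0]
    if mode == "within_cluster":
        if clusters is None:
            raise ValueError("within_cluster mode requires cluster labels")
        clusters = np.asarray(clusters)
        groups = [np.flatnonzero(clusters == c) for c in np.unique(clusters)]
        if all(g.size < 2 for g in groups):
            warnings.warn("all clusters are singletons: degenerate null",
                          stacklevel=2)
    elif mode != "global":
        raise ValueError(f"unknown mode {mode!r}")
    null = np.empty(n_perm)
    for i in range(n_perm):
        if mode == "global":
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(g.size)]
        _, null[i] = procrustes_fit(S[perm], G)
    return PermutationTestResult(observed_sse=observed, null_sse=null,
                                 mode=mode)


# ---------------------------------------------------------------------------
# Overlap, peaks, distances
# ---------------------------------------------------------------------------

def dice_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) of two binarized maps over a
    common voxel universe (0 with a warning when both are empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one voxel universe")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 0", stacklevel=2)
        return 0.0
    return float(2.0 * np.sum(a & b) / denom)


def peak_location(values: np.ndarray, coords_mm: np.ndarray,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """mm coordinate of the maximum map value within the (suprathreshold)
    mask; ties broken by the lexicographically smallest coordinate."""
    v = np.asarray(values, dtype=float)
    coords = np.asarray(coords_mm, dtype=float)
    sel = np.ones(v.shape, dtype=bool) if mask is None else \
        np.asarray(mask, dtype=bool)
    sel &= np.isfinite(v)
    if not sel.any():
        raise ValueError("empty (sub-threshold) map: no peak")
    idx = np.flatnonzero(sel)
    vmax = v[idx].max()
    cand = idx[v[idx] >= vmax - 1e-12]
    if cand.size > 1:
        logger.info("peak_location: %d-way tie broken lexicographically",
                    cand.size)
    order = np.lexsort((coords[cand, 2], coords[cand, 1], coords[cand, 0]))
    return coords[cand[order[0]]].copy()


def bilateral_average(left_mm: np.ndarray, right_mm: np.ndarray) -> np.ndarray:
    """Reflect a left-hemisphere peak across the midline (negate x) and
    average with the right-hemisphere peak."""
    left = np.asarray(left_mm, dtype=float).copy()
    right = np.asarray(right_mm, dtype=float)
    left[0] = -left[0]
    return (left + right) / 2.0


def distance_relationships(cortical_distance: np.ndarray,
                           overlap: np.ndarray,
                           cluster_labels: np.ndarray) -> dict:
    """Correlate cortical distance with map overlap (or peak distance) per
    cluster-pair stratum.

    Upper-triangle area pairs are stratified into within-cluster sets (one
    per cluster) and a between-cluster set; each stratum reports Pearson r
    and the pair count n, omitted (logged) when fewer than 3 pairs.
    """
    D = np.asarray(cortical_distance, dtype=float)
    O = np.asarray(overlap, dtype=float)
    labels = np.asarray(cluster_labels)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    strata = {"overall": np.ones(iu.size, dtype=bool),
              "between": labels[iu] != labels[ju]}
    for c in np.unique(labels):
        strata[f"within_{c}"] = (labels[iu] == c) & (labels[ju] == c)
    out = {}
    for name, sel in strata.items():
        ok = sel & np.isfinite(D[iu, ju]) & np.isfinite(O[iu, ju])
        n_pairs = int(ok.sum())
        if n_pairs < 3:
            logger.info("distance_relationships: stratum %s has %d pairs; "
                        "r omitted", name, n_pairs)
            out[name] = {"r": np.nan, "n": n_pairs}
            continue
        r, p = stats.pearsonr(D[iu, ju][ok], O[iu, ju][ok])
        out[name] = {"r": float(r), "n": n_pairs, "p": float(p)}
    return out


def fisher_z_difference(r1: float, n1: int, r2: float, n2: int,
                        ) -> tuple[float, float]:
    """z test for the difference of two independent correlations:
    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).

    Note: applied to correlations that share areas this is approximate (the
    samples are not independent).
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def plot_mds(coords: np.ndarray, labels: np.ndarray | None = None,
             names: list | None = None, ax=None):
    """2-D scatter of an MDS configuration, coloured by cluster label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    labels = np.zeros(len(coords), int) if labels is None else \
        np.asarray(labels)
    for c in np.unique(labels):
        sel = labels == c
        ax.scatter(coords[sel, 0], coords[sel, 1], label=f"cluster {c}")
    if names is not None:
        for (x, y), name in zip(coords, names):
            ax.annotate(str(name), (x, y), fontsize=7,
                        xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.legend(frameon=False)
    return ax


def peak_cluster(peaks_mm: np.ndarray) -> np.ndarray:
    """Cluster connectivity-map peaks by their Euclidean distances.

    Builds a Gaussian affinity graph exp(-d^2 / (2 bw^2)) with bandwidth set
    to the median pairwise distance, then applies spectral modularity
    clustering.  All-coincident points form a single cluster.
    """
    P = np.asarray(peaks_mm, dtype=float)
    if P.shape[0] < 3:
        raise ValueError("peak clustering needs at least 3 peaks")
    d = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(P.shape[0], k=1)
    bw = np.median(d[iu])
    if bw == 0:
        return np.zeros(P.shape[0], dtype=int)
    A = np.exp(-d**2 / (2.0 * bw**2))
    np.fill_diagonal(A, 0.0)
    return spectral_clusters(A)
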