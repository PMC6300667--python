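"""Network structure: map similarity, classical MDS, spectral modularity,
Procrustes permutation tests, Dice, peaks, and distance relationships."""

import numpy as np
import pytest
from itertools import permutations

from pulvicon import netstruct
from pulvicon.netstruct import (bilateral_average, classical_mds,
                                dice_overlap, distance_relationships,
                                fisher_z_difference, map_similarity,
                                peak_cluster, peak_location,
                                permutation_test_mds, procrustes_fit,
                                similarity_to_dissimilarity,
                                spectral_clusters)


class TestMapSimilarity:
    def test_identical_maps_fully_similar(self, rng):
        m = rng.standard_normal((50, 1))
        maps = np.hstack([m, m])
        S = map_similarity(maps)
        assert S[0, 1] == pytest.approx(1.0)

    def test_hand_three_voxel_case_matches_pearson(self):
        maps = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 4.0]])
        S = map_similarity(maps)
        x, y = maps[:, 0], maps[:, 1]
        expected = np.corrcoef(x, y)[0, 1]
        assert S[0, 1] == pytest.approx(expected)

    def test_hemisphere_averaging(self, rng):
        mL = rng.standard_normal((40, 3))
        mR = rng.standard_normal((40, 3))
        S = map_similarity({"L": mL, "R": mR})
        expected = (np.corrcoef(mL.T) + np.corrcoef(mR.T)) / 2
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_constant_map_named_in_error(self, rng):
        maps = rng.standard_normal((30, 2))
        maps[:, 1] = 2.0
        with pytest.raises(ValueError, match="FEF"):
            map_similarity(maps, area_names=["V1", "FEF"])


class TestClassicalMDS:
    def test_two_points_embed_at_their_distance(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        X = classical_mds(D)
        assert np.linalg.norm(X[0] - X[1]) == pytest.approx(3.0)

    def test_collinear_points_reconstructed_exactly(self):
        pos = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        D = np.abs(pos[:, None] - pos[None, :])
        X = classical_mds(D, dims=2)
        rec = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_all_zero_dissimilarity_collapses_to_origin(self):
        X = classical_mds(np.zeros((4, 4)))
        np.testing.assert_allclose(X, 0.0, atol=1e-12)

    def test_euclidean_input_recovered_to_rotation(self, rng):
        pts = rng.standard_normal((8, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        X = classical_mds(D, dims=2)
        rec = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="zero diagonal"):
            classical_mds(np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestSpectralClusters:
    def test_two_disconnected_cliques_split_exactly(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0.0)
        labels = spectral_clusters(W)
        assert labels.max() + 1 == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_complete_uniform_graph_is_one_cluster(self):
        W = np.ones((6, 6))
        np.fill_diagonal(W, 0.0)
        labels = spectral_clusters(W)
        assert labels.max() == 0

    def test_planted_two_block_similarity_recovered(self):
        successes = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            W = np.full((12, 12), 0.1)
            W[:6, :6] = 0.6
            W[6:, 6:] = 0.6
            noise = 0.05 * r.standard_normal((12, 12))
            W = W + (noise + noise.T) / 2
            np.fill_diagonal(W, 0.0)
            labels = spectral_clusters(W)
            ok = (labels.max() + 1 == 2
                  and len(set(labels[:6])) == 1
                  and len(set(labels[6:])) == 1)
            successes += ok
        assert successes >= 19

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty graph"):
            spectral_clusters(np.zeros((4, 4)))

    def test_invariant_to_node_relabeling(self, rng):
        W = np.full((10, 10), 0.1)
        W[:5, :5] = 0.7
        W[5:, 5:] = 0.7
        np.fill_diagonal(W, 0.0)
        labels = spectral_clusters(W)
        perm = rng.permutation(10)
        labels_p = spectral_clusters(W[np.ix_(perm, perm)])
        # partitions must agree up to label names
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_agrees_with_igraph_leading_eigenvector(self):
        igraph = pytest.importorskip("igraph")
        r = np.random.default_rng(5)
        W = np.full((14, 14), 0.15)
        W[:7, :7] = 0.6
        W[7:, 7:] = 0.6
        noise = 0.03 * r.standard_normal((14, 14))
        W = W + (noise + noise.T) / 2
        np.fill_diagonal(W, 0.0)
        labels = spectral_clusters(W)
        g = igraph.Graph.Weighted_Adjacency(W.tolist(), mode="undirected",
                                            attr="weight")
        memb = np.array(
            g.community_leading_eigenvector(weights="weight").membership)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, memb) == 1.0


class TestProcrustes:
    def test_identical_configurations_have_zero_sse(self, rng):
        X = rng.standard_normal((6, 2))
        _, sse = procrustes_fit(X, X.copy())
        assert sse < 1e-12

    def test_rotation_and_scale_absorbed(self, rng):
        X = rng.standard_normal((6, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Y = 2.5 * X @ R.T + np.array([3.0, -1.0])
        _, sse = procrustes_fit(X, Y)
        assert sse < 1e-12

    def test_matches_rotation_grid_search_oracle(self, rng):
        """Four-point case: exhaustive search over rotation angle (with both
        reflections and closed-form optimal scale) agrees to 1e-6."""
        X = rng.standard_normal((4, 2))
        Y = rng.standard_normal((4, 2))
        _, sse = procrustes_fit(X, Y)

        def normalize(M):
            M = M - M.mean(0)
            return M / np.linalg.norm(M)

        Xn, Yn = normalize(X), normalize(Y)
        best = np.inf
        for refl in (1.0, -1.0):
            Xr = Xn * np.array([1.0, refl])
            for th in np.linspace(0, 2 * np.pi, 200001):
                R = np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
                Z = Xr @ R.T
                s = (Z * Yn).sum()          # optimal scale for unit norms
                best = min(best, ((Yn - s * Z) ** 2).sum())
        assert sse == pytest.approx(best, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            procrustes_fit(np.zeros((1, 2)), np.zeros((1, 2)))


class TestPermutationTest:
    def test_matching_configurations_beat_every_permutation(self, rng):
        G = rng.standard_normal((8, 2))
        res = permutation_test_mds(G.copy(), G, n_perm=200, seed=0)
        assert res.observed_sse < res.null_sse.min()
        assert res.percentile <= 1 / 200

    def test_three_point_null_matches_exhaustive_enumeration(self, rng):
        S = rng.standard_normal((3, 2))
        G = rng.standard_normal((3, 2))
        exhaustive = sorted(procrustes_fit(S[list(p)], G)[1]
                            for p in permutations(range(3)))
        res = permutation_test_mds(S, G, n_perm=600, seed=1)
        observed_levels = np.unique(np.round(res.null_sse, 12))
        expected_levels = np.unique(np.round(exhaustive, 12))
        np.testing.assert_allclose(observed_levels, expected_levels,
                                   atol=1e-10)

    def test_fixed_seed_reproducible(self, rng):
        S, G = rng.standard_normal((2, 6, 2))
        r1 = permutation_test_mds(S, G, n_perm=50, seed=3)
        r2 = permutation_test_mds(S, G, n_perm=50, seed=3)
        np.testing.assert_array_equal(r1.null_sse, r2.null_sse)

    def test_within_cluster_mode_respects_cluster_boundaries(self, rng):
        S, G = rng.standard_normal((2, 8, 2))
        clusters = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = permutation_test_mds(S, G, n_perm=50, mode="within_cluster",
                                   clusters=clusters, seed=2)
        assert res.null_sse.shape == (50,)

    def test_singleton_clusters_flagged(self, rng):
        S, G = rng.standard_normal((2, 3, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            permutation_test_mds(S, G, n_perm=10, mode="within_cluster",
                                 clusters=np.array([0, 1, 2]), seed=0)


class TestDiceOverlap:
    def test_identical_nonempty_masks(self):
        m = np.array([True, True, False, True])
        assert dice_overlap(m, m) == 1.0

    def test_disjoint_masks(self):
        assert dice_overlap(np.array([True, False]),
                            np.array([False, True])) == 0.0

    def test_direct_formula_evaluation(self):
        a = np.array([True, True, False, False])
        b = np.array([True, False, True, False])
        assert dice_overlap(a, b) == pytest.approx(0.5)

    def test_empty_masks_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert dice_overlap(np.zeros(3, bool), np.zeros(3, bool)) == 0.0


class TestPeaks:
    def test_single_suprathreshold_voxel_is_the_peak(self):
        vals = np.array([0.1, 0.9, 0.2])
        coords = np.array([[0, 0, 0], [2, 4, 6], [8, 8, 8]], float)
        np.testing.assert_array_equal(peak_location(vals, coords),
                                      [2, 4, 6])

    def test_bilateral_reflection_arithmetic(self):
        out = bilateral_average(np.array([-10.0, -30.0, 5.0]),
                                np.array([12.0, -30.0, 5.0]))
        np.testing.assert_allclose(out, [11.0, -30.0, 5.0])

    def test_exact_tie_broken_lexicographically(self):
        vals = np.array([0.5, 0.5, 0.1])
        coords = np.array([[4, 0, 0], [2, 9, 9], [0, 0, 0]], float)
        np.testing.assert_array_equal(peak_location(vals, coords),
                                      [2, 9, 9])

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peak_location(np.array([1.0]), np.zeros((1, 3)),
                          mask=np.array([False]))


class TestDistanceRelationships:
    def test_exact_linear_anticorrelation(self):
        n = 6
        pos = np.arange(n, dtype=float)
        D = np.abs(pos[:, None] - pos[None, :])
        dice = 1.0 - D / D.max()
        out = distance_relationships(D, dice, np.zeros(n, int))
        assert out["overall"]["r"] == pytest.approx(-1.0)

    def test_shuffled_overlap_uncorrelated_on_average(self):
        rs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = 15
            pos = r.uniform(0, 50, n)
            D = np.abs(pos[:, None] - pos[None, :])
            dice = r.uniform(0, 1, (n, n))
            dice = (dice + dice.T) / 2
            out = distance_relationships(D, dice, np.zeros(n, int))
            rs.append(out["overall"]["r"])
        ci = 1.96 * np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < ci + 0.05

    def test_small_strata_omitted(self):
        D = np.abs(np.arange(4, dtype=float)[:, None]
                   - np.arange(4, dtype=float)[None, :])
        out = distance_relationships(D, 1 - D / 3, np.array([0, 0, 1, 1]))
        assert np.isnan(out["within_0"]["r"])
        assert out["within_0"]["n"] == 1


class TestFisherZDifference:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_difference(0.5, 103, 0.5, 28)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_hand_evaluation(self):
        z, _ = fisher_z_difference(0.6, 50, 0.2, 50)
        assert z == pytest.approx(2.3773, abs=1e-4)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match=r"\|r\| < 1"):
            fisher_z_difference(1.0, 10, 0.5, 10)


class TestPeakCluster:
    def test_two_separated_groups(self, rng):
        P = np.vstack([rng.normal(0, 0.5, (5, 3)),
                       rng.normal(30, 0.5, (5, 3))])
        labels = peak_cluster(P)
        assert labels.max() + 1 == 2

    def test_coincident_points_single_cluster(self):
        labels = peak_cluster(np.zeros((5, 3)))
        assert labels.max() == 0

    def test_planted_three_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        from pulvicon.synthdata import generate_dorsal_peaks
        successes = 0
        for seed in range(20):
            table, _ = generate_dorsal_peaks(seed=seed)
            labels = peak_cluster(table[["x", "y", "z"]].to_numpy())
            successes += (adjusted_rand_score(table["group"], labels) == 1.0)
        assert successes >= 19


def test_mds_procrustes_round_trip():
    """Embedding a configuration's own distance matrix and aligning back to
    the original gives SSE below 1e-6."""
    rng = np.random.default_rng(8)
    pts = rng.standard_normal((10, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    X = classical_mds(D, dims=2)
    _, sse = procrustes_fit(X, pts)
    assert sse < 1e-6


def test_plot_mds_renders_labels_and_clusters(tmp_path, rng):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    coords = rng.standard_normal((6, 2))
    ax = netstruct.plot_mds(coords, labels=np.array([0, 0, 0, 1, 1, 1]),
                            names=[f"a{i}" for i in range(6)])
    ax.figure.savefig(tmp_path / "mds.png")
    plt.close(ax.figure)
    assert (tmp_path / "mds.png").stat().st_size > 0


def test_similarity_to_dissimilarity_is_row_euclidean():
    S = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
    D = similarity_to_dissimilarity(S)
    assert D[0, 1] == pytest.approx(np.linalg.norm(S[0] - S[1]))
    assert np.allclose(np.diag(D), 0.0)
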