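"""Two-step connectivity analysis: profiles, pseudo-group averaging,
second-order similarity maps, group statistics, and the Model/Results API."""

import numpy as np
import pytest
from dataclasses import replace

from pulvicon import PulvinoCorticalModel
from pulvicon.connectivity import (area_profile, group_connectivity,
                                   profile_similarity_map,
                                   pseudo_group_profile,
                                   split_half_reliability, voxel_profiles)


def _pearson_oracle(x, y):
    """Textbook Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum()
                 / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestAreaProfile:
    def test_identical_areas_correlate_perfectly(self, rng):
        x = rng.standard_normal(30)
        R = area_profile(np.stack([x, x.copy()]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_negated_area_correlates_minus_one(self, rng):
        x = rng.standard_normal(30)
        R = area_profile(np.stack([x, -x]))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_on_hand_values(self):
        A = np.array([[1.0, 2.0, 4.0, 3.0],
                      [2.0, 1.0, 3.0, 5.0],
                      [0.0, 1.0, 1.0, 2.0]])
        R = area_profile(A)
        for i in range(3):
            for j in range(3):
                assert R[i, j] == pytest.approx(_pearson_oracle(A[i], A[j]))

    def test_constant_series_named_in_error(self, rng):
        A = rng.standard_normal((3, 20))
        A[1] = 2.0
        with pytest.raises(ValueError, match="FFA"):
            area_profile(A, names=["V1", "FFA", "V2"])


class TestVoxelProfiles:
    def test_voxel_equal_to_area_gives_unit_row_entry(self, rng):
        A = rng.standard_normal((3, 40))
        R = voxel_profiles(A[1][None, :], A)
        assert R[0, 1] == pytest.approx(1.0)

    def test_pure_noise_voxel_has_small_correlations(self):
        r = np.random.default_rng(0)
        A = r.standard_normal((4, 1000))
        v = r.standard_normal((1, 1000))
        assert np.max(np.abs(voxel_profiles(v, A))) < 0.1

    def test_hand_case_matches_pearson_oracle(self):
        V = np.array([[1.0, 3.0, 2.0, 5.0], [0.0, 1.0, 0.0, 2.0]])
        A = np.array([[2.0, 2.0, 3.0, 4.0], [1.0, 0.0, 2.0, 1.0]])
        R = voxel_profiles(V, A)
        for v in range(2):
            for a in range(2):
                assert R[v, a] == pytest.approx(_pearson_oracle(V[v], A[a]))


class TestPseudoGroupProfile:
    def test_two_subjects_excluding_one_returns_the_other(self, rng):
        p1 = np.corrcoef(rng.standard_normal((4, 30)))
        p2 = np.corrcoef(rng.standard_normal((4, 30)))
        out = pseudo_group_profile({"a": p1, "b": p2}, "a")
        np.testing.assert_allclose(out, p2, atol=1e-10)

    def test_identical_subjects_return_common_profile(self, rng):
        p = np.corrcoef(rng.standard_normal((4, 30)))
        out = pseudo_group_profile({"a": p, "b": p.copy(), "c": p.copy()},
                                   "c")
        np.testing.assert_allclose(out, p, atol=1e-10)

    def test_fisher_z_mean_closed_form(self):
        p1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        p2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = pseudo_group_profile({"a": p1, "b": p2, "c": p1}, "c")
        expected = np.tanh((np.arctanh(0.0) + np.arctanh(0.5)) / 2)
        assert out[0, 1] == pytest.approx(expected)

    def test_excluding_last_subject_rejected(self, rng):
        p = np.corrcoef(rng.standard_normal((3, 20)))
        with pytest.raises(ValueError, match="no subjects"):
            pseudo_group_profile({"a": p}, "a")

    def test_excluded_subject_data_never_enters(self, rng):
        profiles = {s: np.corrcoef(rng.standard_normal((4, 30)))
                    for s in "abc"}
        ref = pseudo_group_profile(profiles, "a")
        profiles["a"] = np.corrcoef(rng.standard_normal((4, 30)))
        np.testing.assert_array_equal(ref,
                                      pseudo_group_profile(profiles, "a"))


class TestProfileSimilarityMap:
    def test_voxel_matching_area_profile_scores_one(self, rng):
        G = np.corrcoef(rng.standard_normal((5, 60)))
        vox = G[2][None, :]             # voxel profile = area 2's profile
        M = profile_similarity_map(vox, G)
        assert M[0, 2] == pytest.approx(1.0)

    def test_anticorrelated_profile_scores_minus_one(self, rng):
        G = np.corrcoef(rng.standard_normal((5, 60)))
        cols = np.delete(np.arange(5), 2)
        g = G[2, cols]
        vox = np.zeros((1, 5))
        vox[0, cols] = -(g - g.mean()) + g.mean()   # reflect around the mean
        M = profile_similarity_map(vox, G)
        assert M[0, 2] == pytest.approx(-1.0)

    def test_invariant_to_common_area_reordering(self, rng):
        G = np.corrcoef(rng.standard_normal((6, 80)))
        V = rng.uniform(-0.5, 0.5, size=(4, 6))
        M = profile_similarity_map(V, G)
        perm = rng.permutation(6)
        M_perm = profile_similarity_map(V[:, perm], G[np.ix_(perm, perm)])
        np.testing.assert_allclose(M_perm, M[:, perm], atol=1e-10)

    def test_one_hot_voxels_recover_their_driving_area(self):
        """argmax over areas identifies the planted area in >= 95% of
        voxels across seeds."""
        from pulvicon.synthdata import generate_resting_dataset
        hits = total = 0
        for seed in range(10):
            from pulvicon.datatypes import SimulationConfig
            areas = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(4)]
            cfg = SimulationConfig(
                n_subjects=3, area_names=areas,
                network_assignment={a: a[0] for a in areas},
                grid_shape=(2, 4, 4), n_timepoints=200, bilateral=False,
                topography_kind="one_hot", noise_sd=0.3,
                drift_amplitude=0.0, nuisance_amplitude=0.0,
                area_corr_length=2.0, topography_corr=0.25, seed=seed)
            datasets, area_set, truth = generate_resting_dataset(cfg)
            d = datasets[0]
            A = area_set.series[d.subject_id]
            G = area_profile(A)
            V = voxel_profiles(d.voxel_series, A)
            M = profile_similarity_map(V, G)
            planted = np.argmax(
                np.abs(d.voxel_series @ A.T), axis=1)  # one-hot assignment
            rec = np.nanargmax(M, axis=1)
            hits += int((rec == planted).sum())
            total += d.n_voxels
        assert hits / total >= 0.95

    def test_area_ordering_mismatch_rejected(self, rng):
        G = np.corrcoef(rng.standard_normal((5, 30)))
        with pytest.raises(ValueError, match="ordering mismatch"):
            profile_similarity_map(rng.standard_normal((2, 4)), G)


class TestGroupConnectivity:
    def test_identical_subject_maps_average_to_input(self, rng):
        m = rng.uniform(-0.8, 0.8, size=(20, 3))
        with pytest.warns(UserWarning, match="constant"):
            out = group_connectivity([m, m.copy(), m.copy()])
        np.testing.assert_allclose(out.mean, m, atol=1e-10)
        assert not np.isfinite(out.t).any()

    def test_null_maps_control_false_positive_rate(self):
        fractions = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            maps = [np.clip(0.3 * r.standard_normal((150, 2)), -0.99, 0.99)
                    for _ in range(10)]
            out = group_connectivity(maps, q=0.05)
            fractions.append(np.mean(out.q < 0.05))
        assert np.mean(fractions) <= 0.05

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            group_connectivity([rng.standard_normal((10, 2))])


class TestSplitHalfReliability:
    def test_identical_subjects_perfectly_reliable(self, rng):
        m = rng.uniform(-0.5, 0.5, size=(30, 4))
        out = split_half_reliability([m.copy() for _ in range(6)],
                                     iterations=20, seed=0)
        assert out["mean"] == pytest.approx(1.0)

    def test_independent_noise_maps_unreliable(self):
        r = np.random.default_rng(3)
        maps = [np.clip(0.3 * r.standard_normal((200, 3)), -0.99, 0.99)
                for _ in range(12)]
        out = split_half_reliability(maps, iterations=100, seed=1)
        assert abs(out["mean"]) < 0.1

    def test_fixed_seed_reproducible(self, rng):
        maps = [rng.uniform(-0.5, 0.5, size=(30, 2)) for _ in range(5)]
        o1 = split_half_reliability(maps, iterations=25, seed=9)
        o2 = split_half_reliability(maps, iterations=25, seed=9)
        np.testing.assert_array_equal(o1["iterations"], o2["iterations"])


class TestModelResults:
    def test_fit_smoke_and_summary(self, small_config):
        model, truth = PulvinoCorticalModel.from_simulation(small_config)
        res = model.fit()
        S = res.map_similarity()
        assert S.shape == (10, 10)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert np.all(S <= 1 + 1e-9) and np.all(S >= -1 - 1e-9)
        text = res.summary()
        assert "clusters found" in text

    def test_mds_first_axis_carries_most_variance(self, small_config):
        model, _ = PulvinoCorticalModel.from_simulation(small_config)
        coords = model.fit().mds()
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_missing_area_series_rejected(self, small_config):
        from pulvicon.synthdata import generate_resting_dataset
        datasets, area_set, _ = generate_resting_dataset(small_config)
        del area_set.series[datasets[0].subject_id]
        with pytest.raises(ValueError, match="missing"):
            PulvinoCorticalModel(datasets, area_set)

    def test_reduced_parcellation_reaches_same_conclusion(self, small_config):
        """Network recovery agrees between the full area set and a reduced
        one (the parcellation-robustness property)."""
        from sklearn.metrics import adjusted_rand_score
        cfg = replace(small_config, n_subjects=6)
        model, truth = PulvinoCorticalModel.from_simulation(cfg)
        full = model.fit()
        full_labels = full.clusters()
        reduced_names = [n for i, n in enumerate(cfg.area_names)
                         if i % 3 != 2]   # drop a third of the areas
        sub = model.area_set.subset(reduced_names)
        reduced = PulvinoCorticalModel(model.datasets, sub).fit()
        red_labels = reduced.clusters()
        planted_full = [truth.network_assignment[n] for n in full.area_names]
        planted_red = [truth.network_assignment[n]
                       for n in reduced.area_names]
        assert adjusted_rand_score(planted_full, full_labels) == 1.0
        assert adjusted_rand_score(planted_red, red_labels) == 1.0
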