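"""Map-similarity battery: Spearman/Dice, subsampling, Mantel, SNR filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cofluct.edges import EdgeIndex, vector_to_matrix
from cofluct.similarity import (
    activation_filter,
    cohens_d,
    dice,
    distance_matrix,
    edge_subsample_similarity,
    mantel,
    paired_similarity_test,
    regionwise_similarity,
    similarity_vs_n,
    snr_filter,
    spearman_map,
    subject_level_similarity,
    subject_similarities,
)


class TestSpearman:
    def test_perfect_and_reversed(self, rng):
        a = rng.normal(size=20)
        assert spearman_map(a, a) == 1.0
        assert spearman_map(a, -a) == -1.0

    def test_hand_rank_example(self):
        assert abs(spearman_map([1, 2, 3, 4], [1, 3, 2, 4]) - 0.8) < 1e-12

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            spearman_map([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=15), rng.normal(size=15)
        base = spearman_map(a, b)
        assert abs(spearman_map(np.exp(a), b) - base) < 1e-12
        assert abs(spearman_map(a, b**3) - base) < 1e-12


class TestDice:
    def test_identical_nonempty(self):
        m = np.array([1, 0, 1, 1], dtype=bool)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        assert dice(np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool)) == 0.0

    def test_half_overlap(self):
        assert dice(np.array([1, 1, 0, 0], bool), np.array([1, 0, 1, 0], bool)) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0

    def test_symmetric(self, rng):
        a = rng.uniform(size=30) > 0.5
        b = rng.uniform(size=30) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_signed_variant_discounts_sign_disagreement(self):
        mask = np.ones(2, dtype=bool)
        assert dice(mask, mask, signs_a=np.array([1.0, -1.0]), signs_b=np.array([1.0, 1.0])) == 0.5


class TestSimilarityVsN:
    def test_identical_tasks_give_rho_one(self, rng):
        maps = rng.normal(0.3, 1.0, size=(10, 50))
        curves = similarity_vs_n(maps, maps, n_grid=[4, 8], n_repeats=3, seed=0)
        assert np.allclose(curves["rho_mean"], 1.0)

    def test_full_sample_has_zero_spread(self, rng):
        a = rng.normal(size=(8, 40))
        b = rng.normal(size=(8, 40))
        curves = similarity_vs_n(a, b, n_grid=[8], n_repeats=5, seed=0)
        assert curves["rho_sd"].iloc[0] == 0.0

    def test_shared_structure_similarity_grows_with_n(self, rng):
        common = rng.normal(size=60)
        a = common + rng.normal(scale=2.0, size=(24, 60))
        b = common + rng.normal(scale=2.0, size=(24, 60))
        curves = similarity_vs_n(a, b, n_grid=[4, 24], n_repeats=8, seed=1)
        assert curves["rho_mean"].iloc[1] > curves["rho_mean"].iloc[0]


class TestEdgeSubsample:
    def test_identical_maps(self, rng):
        m = rng.normal(size=100)
        rhos = edge_subsample_similarity(m, m, k=20, n_reps=50, seed=0)
        assert np.allclose(rhos, 1.0)

    def test_full_subset_equals_full_map(self, rng):
        a, b = rng.normal(size=60), rng.normal(size=60)
        rhos = edge_subsample_similarity(a, b, k=60, n_reps=10, seed=0)
        assert np.allclose(rhos, spearman_map(a, b))

    def test_subsample_mean_consistent_with_full_map(self, rng):
        common = rng.normal(size=500)
        a = common + rng.normal(size=500)
        b = common + rng.normal(size=500)
        full = spearman_map(a, b)
        rhos = edge_subsample_similarity(a, b, k=50, n_reps=400, seed=3)
        se = rhos.std(ddof=1) / np.sqrt(rhos.size)
        assert abs(rhos.mean() - full) < 3 * se + 0.02


class TestRegionwise:
    def test_identical_maps_give_all_ones(self, rng):
        idx = EdgeIndex(8)
        m = rng.normal(size=idx.n_edges)
        assert np.allclose(regionwise_similarity(m, m, idx), 1.0)

    def test_profile_length_excludes_diagonal(self):
        idx = EdgeIndex(268)
        M = vector_to_matrix(np.arange(idx.n_edges, dtype=float), idx)
        keep = np.arange(268) != 0
        assert M[0, keep].size == 267

    def test_hand_constructed_four_regions(self):
        idx = EdgeIndex(4)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = -a  # every profile exactly reversed
        out = regionwise_similarity(a, b, idx)
        assert np.allclose(out, -1.0)


class TestSubjectLevel:
    def test_cohens_d_brute_force_values(self):
        with pytest.warns(UserWarning):
            assert np.isnan(cohens_d(np.array([0.0, 0.0, 0.0, 0.0])))
        with pytest.warns(UserWarning):
            assert np.isinf(cohens_d(np.array([1.0, 1.0, 1.0, 1.0])))
        d = np.array([0.0, 2.0, 0.0, 2.0])
        # mean 1, sample sd sqrt(4/3)
        assert abs(cohens_d(d) - 1.0 / np.sqrt(4.0 / 3.0)) < 1e-12
        assert abs(cohens_d(d) - 0.8660254) < 1e-6

    def test_fisher_z_option_preserves_direction(self, rng):
        a = np.clip(rng.uniform(0.2, 0.6, size=10), -0.99, 0.99)
        b = np.clip(a - 0.15, -0.99, 0.99)
        raw = paired_similarity_test(a, b)
        fz = paired_similarity_test(a, b, fisher_z=True)
        assert raw["t"] > 0 and fz["t"] > 0
        assert raw["mean_a"] != fz["mean_a"]

    def test_identical_maps_rho_one_and_sentinel(self, rng):
        maps = rng.normal(size=(5, 30))
        rhos = subject_similarities(maps, maps)
        assert np.allclose(rhos, 1.0)
        with pytest.warns(UserWarning):
            out = paired_similarity_test(rhos, rhos)
        assert np.isnan(out["t"])

    def test_dissociation_cohort_activation_exceeds_network(self, small_cohort):
        from cofluct.pipelines import ActivationGLM, EdgeGLM

        act_a = np.vstack([ActivationGLM().fit(r).beta_ for r in small_cohort.task_a])
        act_b = np.vstack([ActivationGLM().fit(r).beta_ for r in small_cohort.task_b])
        net_a = np.vstack([EdgeGLM().fit(r).contrast_.effect for r in small_cohort.task_a])
        net_b = np.vstack([EdgeGLM().fit(r).contrast_.effect for r in small_cohort.task_b])
        out = subject_level_similarity(
            {"activation": (act_a, act_b), "network": (net_a, net_b)}
        )
        assert out["paired"]["mean_a"] > out["paired"]["mean_b"]


class TestMantel:
    def test_identical_matrices(self, rng):
        D = distance_matrix(rng.normal(size=(8, 25)))
        out = mantel(D, D, n_perm=199, n_resample=50, seed=0)
        assert abs(out["r"] - 1.0) < 1e-12
        assert out["p"] == pytest.approx(1 / 200, abs=0.03)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        A = distance_matrix(rng.normal(size=(10, 30)))
        B = distance_matrix(rng.normal(size=(10, 30)))
        out = mantel(A, B, n_perm=999, n_resample=50, seed=1)
        r_ref, p_ref, _ = skbio_mantel(
            SkbioDM(A), SkbioDM(B), method="pearson", permutations=999, alternative="two-sided"
        )
        assert abs(out["r"] - r_ref) < 1e-10
        assert abs(out["p"] - p_ref) < 0.05

    def test_invariant_to_joint_relabeling(self, rng):
        A = distance_matrix(rng.normal(size=(9, 20)))
        B = distance_matrix(rng.normal(size=(9, 20)))
        perm = rng.permutation(9)
        out1 = mantel(A, B, n_perm=99, n_resample=20, seed=0)
        out2 = mantel(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], n_perm=99, n_resample=20, seed=0)
        assert abs(out1["r"] - out2["r"]) < 1e-12

    def test_planted_common_factor_detected(self, rng):
        # both measures share a subject-level factor: r > 0, CI above 0
        factor = rng.normal(size=(30, 1))
        load_a = rng.normal(size=(1, 80))
        load_b = rng.normal(size=(1, 80))
        maps_a = factor @ load_a + 0.2 * rng.normal(size=(30, 80))
        maps_b = factor @ load_b + 0.2 * rng.normal(size=(30, 80))
        out = mantel(
            distance_matrix(maps_a),
            distance_matrix(maps_b),
            n_perm=499,
            n_resample=300,
            resample_ratio=0.3,
            seed=2,
        )
        assert out["r"] > 0
        assert out["p"] < 0.01
        assert out["ci"][0] > 0

    def test_small_matrix_raises(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((3, 3)), np.zeros((3, 3)))


class TestSnrFilter:
    def test_zero_mean_contrast_retains_nothing(self, rng):
        betas = rng.normal(0.0, 1.0, size=(200, 50))
        out = snr_filter({"task": betas}, threshold=0.5)
        assert abs(out["median"]["task"]) < 0.2
        assert out["retained"].size < 3

    def test_known_effect_size_recovered(self, rng):
        betas = rng.normal(1.0, 1.0, size=(200, 300))
        out = snr_filter({"task": betas}, threshold=0.5)
        assert abs(out["median"]["task"] - 1.0) < 0.2
        assert out["retained"].size > 250

    def test_disjoint_high_snr_sets_intersect_empty(self, rng):
        a = np.tile([3.0, 0.0], (10, 1)) + 0.1 * rng.normal(size=(10, 2))
        b = np.tile([0.0, 3.0], (10, 1)) + 0.1 * rng.normal(size=(10, 2))
        out = snr_filter({"a": a, "b": b}, threshold=0.5)
        assert out["retained"].size == 0


class TestActivationFilter:
    def test_single_region_above_threshold_in_both_tasks(self, rng):
        a = 0.05 * rng.normal(size=(20, 5))
        b = 0.05 * rng.normal(size=(20, 5))
        a[:, 3] += 1.0
        b[:, 3] += 1.0
        retained = activation_filter({"a": a, "b": b}, d_threshold=0.8)
        assert retained.tolist() == [3]

    def test_infinite_threshold_empties(self, rng):
        a = rng.normal(size=(10, 4))
        assert activation_filter({"a": a}, d_threshold=np.inf).size == 0
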