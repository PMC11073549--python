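"""Design-matrix construction: HRF, FIR, cosine drift, motion, presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cofluct.data import Confounds
from cofluct.regressors import (
    DesignError,
    DesignMatrix,
    TaskDesign,
    activation_design,
    build_design,
    cosine_basis,
    denoise_design,
    double_gamma_hrf,
    edge_design,
    expand_motion,
    fir_basis,
    hrf_triplet,
)


def _one_block(cond="congruent", onset=10.0, dur=20.0, n_frames=100, tr=2.0):
    return TaskDesign([(cond, onset, dur)], n_frames=n_frames, tr=tr)


class TestTaskDesign:
    def test_blocks_sorted_and_validated(self):
        d = TaskDesign(
            [("incongruent", 50.0, 10.0), ("congruent", 10.0, 10.0)], n_frames=50, tr=2.0
        )
        assert [b[1] for b in d.blocks] == [10.0, 50.0]
        assert d.conditions == ["congruent", "incongruent"]

    @pytest.mark.parametrize(
        "blocks",
        [
            [("congruent", 10.0, 20.0), ("incongruent", 15.0, 10.0)],  # overlap
            [("congruent", 90.0, 20.0)],  # extends past run end (100 frames TR 1)
            [("congruent", -1.0, 5.0)],  # negative onset
        ],
    )
    def test_invalid_blocks_raise(self, blocks):
        with pytest.raises(DesignError):
            TaskDesign(blocks, n_frames=100, tr=1.0)

    def test_boxcar_half_open_interval(self):
        d = _one_block(onset=10.0, dur=20.0, tr=2.0)
        box = d.boxcar("congruent")
        # frame time t in [10, 30) -> frames 5..14
        assert np.flatnonzero(box).tolist() == list(range(5, 15))


class TestHrfTriplet:
    def test_condition_without_blocks_gives_zeros(self):
        d = _one_block("congruent")
        cols, names, roles = hrf_triplet(d, "incongruent")
        assert cols.shape == (100, 3)
        assert np.all(cols == 0)
        assert roles == ["task_main", "task_derivative", "task_derivative"]

    def test_unknown_condition_raises(self):
        with pytest.raises(DesignError, match="condition"):
            hrf_triplet(_one_block(), "neutral")

    def test_impulse_response_is_sampled_kernel(self):
        # a single 1-frame event at t=0 convolved with the kernel returns
        # the kernel itself on the TR grid
        tr = 2.0
        d = TaskDesign([("congruent", 0.0, tr)], n_frames=40, tr=tr)
        col = hrf_triplet(d, "congruent")[0][:, 0]
        t = np.arange(40) * tr
        within = t <= 32.0  # kernel support
        assert np.allclose(col[within], double_gamma_hrf(t[within]), atol=1e-12)
        assert np.all(col[~within] == 0)
        # the analytic kernel tail beyond 32 s is negligible
        assert np.all(np.abs(double_gamma_hrf(t[~within])) < 1e-4)
        # grid peak sits within one frame of the kernel's analytic peak
        # (the kernel is nearly flat between 4 and 6 s, so the argmax may
        # land on either neighbour of the 5-s analytic peak)
        fine = np.linspace(0, 32, 32001)
        analytic_peak = fine[np.argmax(double_gamma_hrf(fine))]
        assert abs(t[np.argmax(col)] - analytic_peak) <= tr

    def test_boxcar_variant_is_raw_indicator(self):
        d = _one_block(onset=10.0, dur=20.0, tr=2.0)
        cols, names, roles = hrf_triplet(d, "congruent", model="boxcar")
        assert cols.shape == (100, 1)
        expected = np.zeros(100)
        expected[5:15] = 1.0
        assert np.array_equal(cols[:, 0], expected)

    def test_linearity_over_disjoint_block_sets(self):
        d_a = TaskDesign([("congruent", 10.0, 20.0)], n_frames=120, tr=2.0)
        d_b = TaskDesign([("congruent", 100.0, 30.0)], n_frames=120, tr=2.0)
        d_ab = TaskDesign(
            [("congruent", 10.0, 20.0), ("congruent", 100.0, 30.0)], n_frames=120, tr=2.0
        )
        for k in range(3):
            col = (
                hrf_triplet(d_a, "congruent")[0][:, k]
                + hrf_triplet(d_b, "congruent")[0][:, k]
            )
            assert np.allclose(col, hrf_triplet(d_ab, "congruent")[0][:, k], atol=1e-10)

    def test_matches_reference_spm_kernel_shape(self):
        # independent cross-check against nilearn's SPM HRF
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        dt = 0.1
        ref = spm_hrf(1.0, oversampling=10)  # sampled every 0.1 s
        mine = double_gamma_hrf(np.arange(0, 32, dt))
        n = min(ref.size, mine.size)
        # nilearn shifts its kernel by one sample (bin-edge convention);
        # compare shapes at the best sub-frame alignment
        corr = max(np.corrcoef(mine[: n - s], ref[s:n])[0, 1] for s in range(3))
        assert corr > 0.999


class TestFirBasis:
    def test_two_conditions_twelve_lags_give_24_columns(self):
        d = TaskDesign(
            [("congruent", 20.0, 60.0), ("incongruent", 120.0, 60.0)], n_frames=280, tr=2.0
        )
        values, names, roles = fir_basis(d, n_lags=12)
        assert values.shape == (280, 24)
        assert set(roles) == {"fir"}

    def test_single_event_produces_shifted_deltas(self):
        d = TaskDesign([("congruent", 0.0, 2.0)], n_frames=50, tr=2.0)
        values, _, _ = fir_basis(d, n_lags=3, conditions=["congruent"])
        for k in range(3):
            assert np.flatnonzero(values[:, k]).tolist() == [k]

    def test_block_shifts_truncate_at_run_end(self):
        d = TaskDesign([("congruent", 8.0, 6.0)], n_frames=60, tr=2.0)  # frames 4..6
        values, _, _ = fir_basis(d, n_lags=2, conditions=["congruent"])
        assert np.flatnonzero(values[:, 0]).tolist() == [4, 5, 6]
        assert np.flatnonzero(values[:, 1]).tolist() == [5, 6, 7]

    def test_fir_span_longer_than_run_raises(self):
        d = TaskDesign([("congruent", 0.0, 2.0)], n_frames=10, tr=2.0)
        with pytest.raises(DesignError):
            fir_basis(d, n_lags=11)

    def test_lag_columns_conserve_stimulus_mass_for_interior_events(self):
        d = TaskDesign([("congruent", 20.0, 10.0)], n_frames=100, tr=2.0)
        n_lags = 4
        values, _, _ = fir_basis(d, n_lags=n_lags, conditions=["congruent"])
        n_stim = int(d.boxcar("congruent").sum())
        assert values.sum() == n_lags * n_stim


class TestCosineBasis:
    @pytest.mark.parametrize(
        "n_frames,tr,cutoff,expected",
        [(280, 2.0, 187.0, 5), (100, 2.0, 1e9, 0), (100, 2.0, 100.0, 3)],
    )
    def test_column_counts(self, n_frames, tr, cutoff, expected):
        values, names, roles = cosine_basis(n_frames, tr, cutoff)
        assert values.shape == (n_frames, expected)

    def test_columns_unit_normalized_and_orthogonal(self):
        values, _, _ = cosine_basis(280, 2.0, 187.0)
        gram = values.T @ values
        assert np.allclose(gram, np.eye(values.shape[1]), atol=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_frames=st.integers(20, 400),
        tr=st.floats(0.5, 4.0),
        cutoff=st.floats(10.0, 500.0),
        factor=st.floats(1.01, 3.0),
    )
    def test_count_monotone_in_cutoff_and_duration(self, n_frames, tr, cutoff, factor):
        base = cosine_basis(n_frames, tr, cutoff)[0].shape[1]
        assert cosine_basis(n_frames, tr, cutoff * factor)[0].shape[1] <= base
        assert cosine_basis(int(n_frames * factor), tr, cutoff)[0].shape[1] >= base


class TestExpandMotion:
    def test_24_columns_in_documented_order(self, rng):
        values, names, _ = expand_motion(rng.normal(size=(30, 6)))
        assert values.shape == (30, 24)
        assert names[0] == "trans_x" and names[6].endswith("derivative1")
        assert all(n.endswith("power2") for n in names[12:])

    def test_constant_column_has_zero_derivative(self):
        motion = np.ones((10, 6))
        values, _, _ = expand_motion(motion)
        assert np.all(values[:, 6:12] == 0)

    def test_hand_example(self):
        motion = np.zeros((3, 6))
        motion[:, 0] = [0, 1, 3]
        values, _, _ = expand_motion(motion)
        assert values[:, 6].tolist() == [0, 1, 2]  # backward difference
        assert values[:, 12].tolist() == [0, 1, 9]  # square of original
        assert values[:, 18].tolist() == [0, 1, 4]  # square of derivative

    def test_wrong_column_count_raises(self):
        with pytest.raises(DesignError):
            expand_motion(np.zeros((10, 5)))


class TestBuildDesign:
    def test_edge_preset_has_seven_columns(self, task_design):
        dm = edge_design(task_design)
        assert dm.n_columns == 7
        assert dm.names[-1] == "intercept"

    def test_denoise_preset_has_57_columns(self, rng, task_design):
        conf = Confounds(
            motion=rng.normal(size=(280, 6)),
            white_matter=rng.normal(size=280),
            csf=rng.normal(size=280),
            global_signal=rng.normal(size=280),
        )
        dm = denoise_design(task_design, conf)
        assert dm.n_columns == 24 + 24 + 1 + 1 + 1 + 5 + 1
        assert sum(r == "fir" for r in dm.roles) == 24
        # global-signal column removable
        assert denoise_design(task_design, conf, gsr=False).n_columns == 56
        # activation preset swaps FIR for HRF triplets
        assert activation_design(task_design, conf).n_columns == 6 + 24 + 3 + 5 + 1

    def test_empty_parts_with_intercept(self):
        dm = build_design([], include_intercept=True, n_frames=10)
        assert dm.n_columns == 1
        assert np.all(dm.values == 1.0)

    def test_frame_mismatch_raises(self):
        a = (np.ones((10, 1)), ["a"], ["motion"])
        b = (np.ones((12, 1)), ["b"], ["motion"])
        with pytest.raises(DesignError, match="frame"):
            build_design([a, b])

    def test_duplicate_names_raise(self):
        a = (np.ones((10, 1)), ["a"], ["motion"])
        with pytest.raises(DesignError, match="duplicate"):
            build_design([a, a], include_intercept=False)

    def test_contrast_vector_lookup(self, task_design):
        dm = edge_design(task_design)
        c = dm.contrast_vector({"incongruent": 1.0, "congruent": -1.0})
        assert c[dm.names.index("incongruent")] == 1.0
        assert c[dm.names.index("congruent")] == -1.0
        assert np.sum(c != 0) == 2
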