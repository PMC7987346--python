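import numpy as np
import pytest
from scipy import stats

from dgne import network_events as ne
from dgne.core_io import Epochs

from conftest import brute_force_window_counts


class TestWindowCounts:
    def test_all_zero_raster(self):
        assert ne.window_counts(np.zeros((5, 20), dtype=int)).sum() == 0

    def test_same_cell_counted_once(self):
        raster = np.zeros((3, 30), dtype=int)
        raster[0, 10] = raster[0, 11] = 1  # two onsets of one cell
        counts = ne.window_counts(raster)
        assert counts[10] == 1 and counts[11] == 1

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ne.window_counts(np.zeros((2, 10), dtype=int), window_frames=4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raster = (rng.random((20, 300)) < 0.03).astype(int)
        np.testing.assert_array_equal(
            ne.window_counts(raster), brute_force_window_counts(raster)
        )


class TestShuffles:
    @pytest.fixture()
    def raster_and_epochs(self):
        rng = np.random.default_rng(2)
        raster = (rng.random((15, 600)) < 0.02).astype(np.int8)
        epochs = Epochs(run=((0, 200), (400, 500)), rest=((200, 400), (500, 600)),
                        n_frames=600)
        return raster, epochs

    @pytest.mark.parametrize("method", ne.SHUFFLE_METHODS)
    def test_per_cell_onset_counts_conserved(self, raster_and_epochs, method):
        raster, epochs = raster_and_epochs
        out = ne.shuffle_raster(raster, method, epochs, seed=0)
        np.testing.assert_array_equal(out.sum(axis=1), raster.sum(axis=1))

    def test_state_constrained_conserves_counts_per_state(self, raster_and_epochs):
        raster, epochs = raster_and_epochs
        out = ne.shuffle_raster(raster, "state_constrained", epochs, seed=1)
        for state in ("run", "rest"):
            m = epochs.mask(state)
            np.testing.assert_array_equal(
                out[:, m].sum(axis=1), raster[:, m].sum(axis=1)
            )

    def test_trace_shift_preserves_inter_onset_structure(self):
        def circular_gaps(onsets, n):
            o = np.sort(onsets)
            return sorted(np.diff(np.concatenate([o, [o[0] + n]])).tolist())

        raster = np.zeros((1, 100), dtype=np.int8)
        raster[0, [10, 13, 50]] = 1
        out = ne.shuffle_raster(raster, "trace_shift", seed=3)
        onsets = np.flatnonzero(out[0])
        assert len(onsets) == 3
        assert circular_gaps(onsets, 100) == circular_gaps([10, 13, 50], 100)

    def test_zero_raster_stays_zero(self):
        z = np.zeros((4, 50), dtype=np.int8)
        for method in ("redistribute", "trace_shift"):
            assert ne.shuffle_raster(z, method, seed=0).sum() == 0

    def test_state_constrained_requires_epochs(self):
        with pytest.raises(ValueError):
            ne.shuffle_raster(np.zeros((2, 10), dtype=np.int8), "state_constrained")


class TestSizeThreshold:
    def test_alpha_one_gives_minimum_threshold(self):
        rng = np.random.default_rng(4)
        raster = (rng.random((20, 500)) < 0.02).astype(np.int8)
        thr, _ = ne.size_threshold(raster, n_shuffles=20, alpha=1.0, seed=0)
        assert thr == 2.0

    def test_sparse_independent_cells_low_threshold(self):
        # chance coincidences among independent sparse cells are small
        rng = np.random.default_rng(5)
        raster = (rng.random((200, 6000)) < 5e-5).astype(np.int8)
        thr, _ = ne.size_threshold(raster, n_shuffles=100, seed=1)
        assert thr <= 3.0

    def test_planted_nes_detectable_below_planted_size(self, default_session,
                                                       default_epochs):
        s, gt = default_session
        thr, curves = ne.size_threshold(s.raster, default_epochs, n_shuffles=100, seed=2)
        assert thr <= 10.0
        assert "redistribute" in curves

    def test_empty_raster_warns_inf(self):
        with pytest.warns(UserWarning):
            thr, _ = ne.size_threshold(np.zeros((3, 50), dtype=np.int8), n_shuffles=5)
        assert np.isinf(thr)

    def test_null_curves_report_extra_methods(self, small_session):
        s, gt = small_session
        from dgne import behavior as beh

        epochs = beh.segment_locomotion(s.speed, s.frame_rate)
        _, curves = ne.size_threshold(
            s.raster, epochs, n_shuffles=10, seed=0,
            report_methods=("trace_shift", "state_constrained"),
        )
        assert set(curves) == set(ne.SHUFFLE_METHODS)


class TestDetection:
    def test_single_contiguous_run_is_one_event(self):
        raster = np.zeros((6, 60), dtype=np.int8)
        raster[:5, 30] = 1  # five cells synchronous at frame 30
        found = ne.detect_network_events(raster, threshold=5)
        assert len(found) == 1
        # the 3-frame window makes counts plateau over frames 29-31;
        # the peak convention picks the earliest frame of the plateau
        assert found.ne_frames[0] == 29
        assert found.ne_members[0] == set(range(5))

    def test_separated_runs_are_two_events(self):
        raster = np.zeros((6, 100), dtype=np.int8)
        raster[:5, 20] = 1
        raster[1:6, 60] = 1
        found = ne.detect_network_events(raster, threshold=5)
        assert len(found) == 2

    def test_threshold_below_two_rejected(self):
        with pytest.raises(ValueError):
            ne.detect_network_events(np.zeros((2, 10), dtype=np.int8), threshold=1)

    def test_detection_invariant_to_cell_order(self):
        rng = np.random.default_rng(6)
        raster = (rng.random((15, 400)) < 0.05).astype(np.int8)
        perm = rng.permutation(15)
        a = ne.detect_network_events(raster, threshold=3)
        b = ne.detect_network_events(raster[perm], threshold=3)
        np.testing.assert_array_equal(a.ne_frames, b.ne_frames)
        # members permute exactly: new index i holds old cell perm[i]
        inv = np.argsort(perm)
        for ma, mb in zip(a.ne_members, b.ne_members):
            assert {int(inv[c]) for c in ma} == mb

    def test_matches_brute_force_on_random_rasters(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            raster = (rng.random((12, 200)) < 0.04).astype(np.int8)
            counts = brute_force_window_counts(raster)
            thr = 3
            found = ne.detect_network_events(raster, thr)
            # event count equals number of maximal supra-threshold runs
            above = counts >= thr
            expected = int(above[0]) + int(np.count_nonzero(above[1:] & ~above[:-1]))
            assert len(found) == expected

    def test_ground_truth_recovery(self, default_session, default_epochs):
        s, gt = default_session
        thr, _ = ne.size_threshold(s.raster, default_epochs, n_shuffles=100, seed=3)
        found = ne.detect_network_events(s.raster, thr)
        matched = sum(
            1 for g in gt.ne_frames if np.any(np.abs(found.ne_frames - g) <= 2)
        )
        assert matched >= 0.9 * len(gt.ne_frames)


class TestStateStats:
    def test_all_rest_nes(self):
        ep = Epochs(run=((0, 300),), rest=((300, 900),), n_frames=900)
        ne_set = ne.NetworkEventSet(
            ne_frames=np.array([400, 500, 600]),
            ne_members=[{0, 1}] * 3,
            size_threshold=2,
        )
        out = ne.ne_state_stats(ne_set, ep, 15.0, seed=0)
        assert out["count_run"] == 0 and out["count_rest"] == 3
        assert out["freq_per_min_run"] == 0.0
        assert out["freq_per_min_rest"] == pytest.approx(3 / (600 / 15 / 60))

    def test_uniform_rest_placement_gives_diagonal_cumulative(self):
        rng = np.random.default_rng(8)
        ep = Epochs(run=(), rest=((0, 30000),), n_frames=30000)
        frames = np.sort(rng.choice(30000, size=200, replace=False))
        ne_set = ne.NetworkEventSet(frames, [{0, 1}] * 200, 2)
        out = ne.ne_state_stats(ne_set, ep, 15.0, seed=1)
        pos = out["rest_period_positions"]
        d = stats.kstest(pos, "uniform").statistic
        assert d < 0.1

    def test_synthetic_rest_frequency_dominates(self, default_session, default_epochs):
        s, gt = default_session
        ne_set = ne.NetworkEventSet(gt.ne_frames, gt.ne_members, 5)
        out = ne.ne_state_stats(ne_set, default_epochs, s.frame_rate, seed=2)
        assert out["freq_per_min_rest"] > out["freq_per_min_run"]
        assert out["equalized"]["rest" if "rest" in out["equalized"] else "run"] >= 0
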