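import numpy as np
import pytest

from dgne import geometry as geo
from dgne.behavior import LapIndex
from dgne.core_io import Epochs
from dgne.synthetic import generate_population_session


def random_orthonormal(n, k, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return q


class TestZscore:
    def test_rows_standardized(self):
        X, kept = geo.zscore_rows(np.array([[1.0, 2.0, 3.0], [5.0, 1.0, 0.0]]))
        np.testing.assert_allclose(X.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=1), 1.0, atol=1e-12)
        assert kept.tolist() == [0, 1]

    def test_constant_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="cells"):
            X, kept = geo.zscore_rows(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
        assert kept.tolist() == [1]
        assert X.shape == (1, 3)

    def test_all_constant_raises(self):
        with pytest.raises(ValueError):
            geo.zscore_rows(np.ones((3, 5)))


class TestPcaBasis:
    def test_rank_one_input(self):
        u = np.array([1.0, -1.0, 0.5])
        X = np.outer(u, np.sin(np.arange(100)))
        b = geo.pca_basis(X)
        assert b.k == 1
        assert b.eigenvalues.size == 1

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 200))
        b = geo.pca_basis(X)
        Xc = X  # W computed on un-centered X by definition X = V W
        np.testing.assert_allclose(b.V @ b.W, Xc, atol=1e-8)

    def test_orthonormal_and_sorted(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 500))
        b = geo.pca_basis(X)
        np.testing.assert_allclose(b.V.T @ b.V, np.eye(b.V.shape[1]), atol=1e-8)
        assert np.all(np.diff(b.eigenvalues) <= 1e-12)
        cum = np.cumsum(b.eigenvalues) / b.eigenvalues.sum()
        assert cum[b.k - 1] >= 0.5

    def test_isotropic_noise_k_band(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 10000))
        b = geo.pca_basis(X)
        assert 20 <= b.k <= 30  # about half the components for isotropic data


class TestExtractStateMatrices:
    def test_window_column_count(self):
        X = np.arange(4 * 900, dtype=float).reshape(4, 900)
        ep = Epochs(run=((0, 100),), rest=((100, 900),), n_frames=900)
        ne_frames = np.array([300, 600])  # 10 s apart at 15 Hz
        X_run, X_net = geo.extract_state_matrices(X, ep, ne_frames)
        assert X_run.shape == (4, 100)
        assert X_net.shape == (4, 2 * 31)  # 2 s window = 31 frames at 15 Hz

    def test_overlapping_windows_deduplicated(self):
        X = np.zeros((2, 500))
        ep = Epochs(run=((0, 50),), rest=((50, 500),), n_frames=500)
        X_run, X_net = geo.extract_state_matrices(X, ep, np.array([100, 110]))
        assert X_net.shape[1] == len(set(range(85, 116)) | set(range(95, 126)))

    def test_no_nes_rejected(self):
        X = np.zeros((2, 100))
        ep = Epochs(run=((0, 50),), rest=((50, 100),), n_frames=100)
        with pytest.raises(ValueError):
            geo.extract_state_matrices(X, ep, np.array([], dtype=int))


class TestProjectedVarianceRatio:
    def test_identity_when_bases_equal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2000))
        V = geo.pca_basis(X).V_k
        assert geo.projected_variance_ratio(X, V, V) == pytest.approx(1.0)

    def test_null_directions_give_zero(self):
        u = np.zeros((5, 1)); u[0] = 1
        X = np.outer(u[:, 0], np.sin(np.arange(300)))
        v_null = np.zeros((5, 1)); v_null[4] = 1
        assert geo.projected_variance_ratio(X, u, v_null) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance_within_subspace(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 3000))
        V = geo.pca_basis(X).V[:, :10]
        q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        ratio_a = geo.projected_variance_ratio(X, V, V)
        ratio_b = geo.projected_variance_ratio(X, V, V @ q)
        assert abs(ratio_a - ratio_b) < 1e-8

    def test_matches_explicit_covariance_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2000))
        V_run = geo.pca_basis(X).V[:, :10]
        V_net = random_orthonormal(100, 10, seed=6)
        # oracle: explicit covariance computed from scratch
        Xc = X - X.mean(axis=1, keepdims=True)
        C = Xc @ Xc.T / (X.shape[1] - 1)
        expected = np.trace(V_net.T @ C @ V_net) / np.trace(V_run.T @ C @ V_run)
        assert geo.projected_variance_ratio(X, V_run, V_net) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            geo.projected_variance_ratio(np.zeros((4, 10)), np.zeros((4, 2)),
                                         np.zeros((5, 2)))


class TestSpcaEros:
    def test_identical_bases(self):
        V = random_orthonormal(20, 3, seed=7)
        s, angles = geo.spca(V, V)
        assert s == pytest.approx(3.0)
        np.testing.assert_allclose(angles, 0.0, atol=1e-6)
        ev = np.array([3.0, 2.0, 1.0])
        assert geo.eros(V, V, ev, ev) == pytest.approx(1.0)

    def test_orthogonal_subspaces(self):
        V_a = np.eye(6)[:, :2]
        V_b = np.eye(6)[:, 2:4]
        s, angles = geo.spca(V_a, V_b)
        assert s == pytest.approx(0.0, abs=1e-12)
        assert geo.eros(V_a, V_b, np.ones(2), np.ones(2)) == pytest.approx(0.0)

    def test_one_dim_bases_at_45_degrees(self):
        V_a = np.array([[1.0], [0.0]])
        V_b = np.array([[np.cos(np.pi / 4)], [np.sin(np.pi / 4)]])
        s, _ = geo.spca(V_a, V_b)
        assert s == pytest.approx(0.5)

    def test_spca_equals_sum_squared_singular_values(self):
        V_a = random_orthonormal(30, 4, seed=8)
        V_b = random_orthonormal(30, 4, seed=9)
        s, _ = geo.spca(V_a, V_b)
        # independent oracle: the trace formula evaluated directly
        expected = float(np.trace(V_a.T @ V_b @ V_b.T @ V_a))
        assert s == pytest.approx(expected)

    def test_eros_hand_built_two_dim(self):
        V_a = np.eye(4)[:, :2]
        V_b = np.zeros((4, 2))
        V_b[0, 0] = 1.0   # component 1 aligned (cos 0 = 1)
        V_b[2, 1] = 1.0   # component 2 orthogonal (cos 90 = 0)
        # weights 0.7 / 0.3 from eigenvalue fractions
        e = geo.eros(V_a, V_b, np.array([7.0, 3.0]), np.array([7.0, 3.0]))
        assert e == pytest.approx(0.7)

    def test_truncation_to_smaller_k(self):
        V_a = random_orthonormal(10, 5, seed=10)
        V_b = V_a[:, :2]
        s, angles = geo.spca(V_a, V_b)
        assert angles.size == 2
        assert s == pytest.approx(2.0)


class TestGeometryShuffleTest:
    def test_shuffle_conservation(self):
        X, ep, nef = generate_population_session(
            n_cells=20, n_run_frames=300, n_nes=4, seed=0
        )
        half = 15
        blocks = np.stack([X[:, f - half : f + half + 1] for f in nef])
        rng = np.random.default_rng(1)
        # method 2: per-window row permutation conserves the window's total
        for i in range(blocks.shape[0]):
            shuf = blocks[i][rng.permutation(20)]
            assert shuf.sum() == pytest.approx(blocks[i].sum())
        # method 3: per-cell permutation across windows conserves each cell's total
        shuf3 = blocks.copy()
        for c in range(20):
            shuf3[rng.permutation(4), c, :] = blocks[:, c, :]
        np.testing.assert_allclose(
            shuf3.sum(axis=(0, 2)), blocks.sum(axis=(0, 2)), atol=1e-9
        )

    def test_invalid_method_rejected(self):
        X, ep, nef = generate_population_session(
            n_cells=10, n_run_frames=200, n_nes=3, seed=2
        )
        with pytest.raises(ValueError):
            geo.geometry_shuffle_test(X, ep, nef, methods=("bogus",), n_shuffles=2)

    def test_replay_positive_detected(self):
        X, ep, nef = generate_population_session(replay=True, seed=3)
        Xz, _ = geo.zscore_rows(X)
        sim = geo.geometry_shuffle_test(Xz, ep, nef, n_shuffles=50, seed=4)
        for m in geo.GEOMETRY_SHUFFLES:
            assert sim.p_values[m]["pvr"] < 0.05

    def test_replay_negative_not_detected(self):
        X, ep, nef = generate_population_session(replay=False, seed=5)
        Xz, _ = geo.zscore_rows(X)
        sim = geo.geometry_shuffle_test(Xz, ep, nef, n_shuffles=50, seed=6)
        assert not all(sim.p_values[m]["pvr"] < 0.05 for m in geo.GEOMETRY_SHUFFLES)


class TestWeightLapAutocorr:
    def lap_index(self, n_laps, frames_per_lap=150):
        lap = np.repeat(np.arange(n_laps), frames_per_lap)
        pos = np.tile(np.linspace(0, 149.0, frames_per_lap), n_laps)
        return LapIndex(lap=lap, within_lap_cm=pos)

    def test_perfectly_periodic_weights_peak_one(self):
        laps = self.lap_index(6)
        w = np.sin(2 * np.pi * laps.within_lap_cm / 150.0)[None, :]
        _, acs, peak = geo.weight_lap_autocorr(w, laps, 150.0, n_components=1)
        assert peak == pytest.approx(1.0, abs=0.02)

    def test_white_noise_weights_low_peak(self):
        laps = self.lap_index(10)
        rng = np.random.default_rng(11)
        w = rng.normal(size=(5, laps.lap.size))
        _, _, peak = geo.weight_lap_autocorr(w, laps, 150.0)
        assert peak < 0.2

    def test_too_few_laps_rejected(self):
        laps = self.lap_index(2)
        with pytest.raises(ValueError):
            geo.weight_lap_autocorr(np.ones((1, laps.lap.size)), laps, 150.0)
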