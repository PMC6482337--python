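import numpy as np
import pytest

from motregress import (
    ConnectivityMatrix,
    distance_dependence,
    fc_matrix,
    modularity_q,
    roi_time_series,
)
from motregress.errors import DegenerateDataError
from motregress.network import partition_modularity


def two_cliques():
    A = np.zeros((8, 8))
    A[:4, :4] = 1.0
    A[4:, 4:] = 1.0
    np.fill_diagonal(A, 1.0)
    coords = np.arange(24, dtype=float).reshape(8, 3)
    return ConnectivityMatrix(A, np.arange(1, 9), coords)


class TestRoiTimeSeries:
    def _img(self, rows, atlas_labels):
        img = np.zeros((len(rows), 1, 1, rows[0].shape[0]))
        atlas = np.zeros((len(rows), 1, 1), dtype=int)
        for i, (r, lab) in enumerate(zip(rows, atlas_labels)):
            img[i, 0, 0] = r
            atlas[i, 0, 0] = lab
        return img, atlas

    def test_single_voxel_roi(self, rng):
        s = rng.normal(size=10)
        img, atlas = self._img([s], [1])
        ts, ids, _ = roi_time_series(img, atlas)
        assert np.allclose(ts[0], s)

    def test_mean_over_members(self, rng):
        s = rng.normal(size=12)
        img, atlas = self._img([s, 3 * s], [2, 2])
        ts, ids, _ = roi_time_series(img, atlas)
        assert ids.tolist() == [2]
        assert np.allclose(ts[0], 2 * s)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grid"):
            roi_time_series(np.zeros((2, 2, 2, 5)), np.zeros((3, 2, 2), dtype=int))

    def test_background_only_raises(self):
        with pytest.raises(DegenerateDataError):
            roi_time_series(np.zeros((2, 2, 2, 5)), np.zeros((2, 2, 2), dtype=int))


class TestFcMatrix:
    def test_duplicate_and_negated_rows(self, rng):
        s = rng.normal(size=20)
        fc = fc_matrix(np.vstack([s, s, -s]))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        assert np.array_equal(np.diag(fc.values), np.ones(3))

    def test_matches_covariance_formula_oracle(self, rng):
        X = rng.normal(size=(3, 4))
        fc = fc_matrix(X)
        for i in range(3):
            for j in range(3):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(fc.values[i, j] - r) < 1e-12

    def test_constant_row_flagged_and_zeroed(self, rng):
        X = np.vstack([rng.normal(size=10), np.full(10, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            fc = fc_matrix(X)
        assert fc.values[0, 1] == 0.0
        assert fc.values[1, 1] == 1.0


class TestDistanceDependence:
    def test_identical_matrices_give_zero_line(self, rng):
        fc = two_cliques()
        fit = distance_dependence(fc, fc)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_slope(self, rng):
        n = 40
        coords = rng.uniform(0, 100, size=(n, 3))
        iu = np.triu_indices(n, k=1)
        d = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
        vals = np.eye(n)
        r = 0.4 - 3.0e-3 * d + rng.normal(0, 1e-4, size=len(d))
        vals[iu] = r
        vals = vals + vals.T - np.diag(np.diag(vals)) + np.eye(n) - np.eye(n)
        np.fill_diagonal(vals, 1.0)
        fc = ConnectivityMatrix(vals, np.arange(n), coords)
        fit = distance_dependence(fc)
        assert fit.slope == pytest.approx(-3.0e-3, rel=1e-2)
        assert fit.slope_ci[0] < -3.0e-3 < fit.slope_ci[1]

    def test_equidistant_rois_degenerate(self):
        fc = two_cliques()
        fc.coords[:] = 0.0
        with pytest.raises(DegenerateDataError):
            distance_dependence(fc)


class TestModularity:
    def test_trivial_partition_scores_zero(self):
        fc = two_cliques()
        assert partition_modularity(fc, [set(range(8))]) == pytest.approx(0.0)

    def test_two_cliques_score_half(self):
        fc = two_cliques()
        q, partition = modularity_q(fc, runs=8, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(partition.values())) == 2

    def test_best_q_beats_trivial_partition(self, subject):
        gm = subject.data.data[subject.data.mask(1)][:60]
        fc = fc_matrix(gm, coords=subject.data.coords[:60])
        q, _ = modularity_q(fc, runs=4, seed=1)
        assert q >= partition_modularity(fc, [set(range(fc.n_rois))])

    def test_scale_invariance(self):
        fc = two_cliques()
        scaled = ConnectivityMatrix(0.3 * fc.values + 0.7 * np.eye(8),
                                    fc.roi_ids, fc.coords)
        # off-diagonal weights scaled by 0.3; Q is weight-scale free
        q1, _ = modularity_q(fc, runs=5, seed=0)
        q2, _ = modularity_q(scaled, runs=5, seed=0)
        assert q1 == pytest.approx(q2)

    def test_more_restarts_never_worse(self):
        fc = two_cliques()
        q_few, _ = modularity_q(fc, runs=1, seed=3)
        q_many, _ = modularity_q(fc, runs=10, seed=3)
        assert q_many >= q_few

    def test_all_negative_graph_degenerate(self):
        vals = -0.5 * np.ones((4, 4)) + 1.5 * np.eye(4)
        fc = ConnectivityMatrix(vals, np.arange(4), np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(DegenerateDataError):
            modularity_q(fc, runs=1, seed=0)

    def test_shared_artifact_raises_fc_and_lowers_q(self, rng):
        """A common additive artifact across all ROIs inflates mean
        connectivity and dissolves community structure."""
        T, n = 120, 24
        base = rng.normal(size=(3, T))
        ts = np.vstack([base[i // 8] + 0.8 * rng.normal(size=T) for i in range(n)])
        clean = fc_matrix(ts)
        shared = 2.0 * rng.normal(size=T)
        dirty = fc_matrix(ts + shared)
        iu = np.triu_indices(n, 1)
        assert dirty.values[iu].mean() > clean.values[iu].mean()
        q_clean, _ = modularity_q(clean, runs=5, seed=0)
        q_dirty, _ = modularity_q(dirty, runs=5, seed=0)
        assert q_dirty < q_clean
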