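import numpy as np
import pytest

from motregress import TrainConfig
from motregress.cnn import (
    REGRESSOR_LABELS,
    _shifted,
    composite_filter,
    conv1d_same,
    forward,
    grad_loss_choice1,
    grad_loss_choice2,
    guarded_correlation,
    init_params,
    loss_choice1,
    loss_choice2,
    standardize_columns,
    train,
)


def windowed_sum_oracle(X, filters, bias):
    """Direct definition of same-padded convolution, loops and all."""
    T, C = X.shape
    f, _, F = filters.shape
    half = f // 2
    out = np.zeros((T, F))
    for t in range(T):
        for j in range(F):
            acc = bias[j]
            for k in range(f):
                ti = t + k - half
                if 0 <= ti < T:
                    acc += X[ti] @ filters[k, :, j]
            out[t, j] = acc
    return out


class TestConv:
    def test_delta_filter_is_identity(self, rng):
        X = rng.normal(size=(12, 1))
        W = np.zeros((5, 1, 1))
        W[2, 0, 0] = 1.0
        assert np.allclose(conv1d_same(X, W, np.zeros(1)), X)

    def test_zero_filters_emit_bias(self):
        out = conv1d_same(np.ones((6, 2)), np.zeros((5, 2, 3)), np.array([1.0, -2.0, 0.5]))
        assert np.allclose(out, np.tile([1.0, -2.0, 0.5], (6, 1)))

    def test_ones_filter_hand_case(self):
        X = np.array([[1.0], [2.0], [3.0]])
        out = conv1d_same(X, np.ones((5, 1, 1)), np.zeros(1))
        assert np.allclose(out.ravel(), [6.0, 6.0, 6.0])

    def test_matches_windowed_sum_oracle(self, rng):
        X = rng.normal(size=(17, 4))
        W = rng.normal(size=(5, 4, 3))
        b = rng.normal(size=3)
        assert np.allclose(conv1d_same(X, W, b), windowed_sum_oracle(X, W, b), atol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            conv1d_same(rng.normal(size=(10, 3)), rng.normal(size=(5, 4, 2)), np.zeros(2))

    def test_even_filter_raises(self, rng):
        with pytest.raises(ValueError, match="odd"):
            conv1d_same(rng.normal(size=(10, 2)), rng.normal(size=(4, 2, 2)), np.zeros(2))


class TestForward:
    def test_zero_input_zero_bias_gives_zero(self):
        p = init_params(0)
        assert np.allclose(forward(np.zeros((20, 6)), p), 0.0)

    def test_linearity_with_zero_biases(self, rng):
        p = init_params(1)
        M1, M2 = rng.normal(size=(2, 30, 6))
        lhs = forward(2.0 * M1 - 0.5 * M2, p)
        rhs = 2.0 * forward(M1, p) - 0.5 * forward(M2, p)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_matches_composite_nine_tap_filter_on_interior(self, rng):
        p = init_params(2)
        p.layer1_bias[:] = rng.normal(size=32)
        p.layer2_bias[:] = rng.normal(size=12)
        M = rng.normal(size=(50, 6))
        out = forward(M, p)
        K, off = composite_filter(p)
        comp = off + sum(_shifted(M, m - 4) @ K[m] for m in range(9))
        assert np.abs(out[4:-4] - comp[4:-4]).max() < 1e-8

    def test_composite_with_identity_first_layer(self):
        p = init_params(3)
        p.layer1_weights[:] = 0.0
        for c in range(6):
            p.layer1_weights[2, c, c] = 1.0   # delta pass-through channels
        p.layer1_bias[:] = 0.0
        K, off = composite_filter(p)
        assert np.allclose(K[2:7, :6, :], p.layer2_weights[:, :6, :])
        assert np.allclose(K[:2], 0.0) and np.allclose(K[7:], 0.0)
        assert np.allclose(off, p.layer2_bias)

    def test_composite_with_zero_second_layer(self):
        p = init_params(4)
        p.layer2_weights[:] = 0.0
        K, off = composite_filter(p)
        assert not K.any()
        assert np.allclose(off, p.layer2_bias)


class TestGuardedCorrelation:
    def test_self_and_negation(self, rng):
        y = rng.normal(size=30)
        assert guarded_correlation(y, y) == pytest.approx(1.0)
        assert guarded_correlation(y, -y) == pytest.approx(-1.0)

    def test_constant_guard(self, rng):
        assert guarded_correlation(np.full(10, 3.0), rng.normal(size=10)) == 0.0


class TestLosses:
    def test_choice1_perfect_fit(self, rng):
        R = rng.normal(size=(25, 12))
        Y = R[:, [0, 3, 7]].T
        assert loss_choice1(Y, R) == pytest.approx(-3.0)

    def test_choice1_orthogonal_series(self, rng):
        # a series orthogonal to the regressor column space has a
        # zero-variance GLM fit -> guarded correlation 0
        R = rng.normal(size=(24, 12))
        y = rng.normal(size=24)
        y -= R @ np.linalg.pinv(R) @ y
        assert loss_choice1(y[None, :], R) == pytest.approx(0.0, abs=1e-8)

    def test_choice1_matches_glm_oracle(self, rng):
        Y = rng.normal(size=(5, 20))
        R = rng.normal(size=(20, 12))
        # independent oracle: explicit normal-equations fit per voxel
        expected = 0.0
        for y in Y:
            beta = np.linalg.solve(R.T @ R, R.T @ y)
            expected -= np.corrcoef(y, R @ beta)[0, 1]
        assert loss_choice1(Y, R) == pytest.approx(expected, abs=1e-10)

    def test_choice2_signed_columns(self, rng):
        R = rng.normal(size=(30, 12))
        Y = np.vstack([R[:, 2], -R[:, 9], 3 * R[:, 5]])
        assert loss_choice2(Y, R) == pytest.approx(-3.0)

    def test_choice2_constant_rows_guarded(self, rng):
        R = rng.normal(size=(15, 12))
        assert loss_choice2(np.ones((4, 15)), R) == 0.0

    def test_choice2_matches_bruteforce_pairs(self, rng):
        Y = rng.normal(size=(3, 18))
        R = rng.normal(size=(18, 2))
        expected = -sum(
            max(abs(np.corrcoef(y, R[:, j])[0, 1]) for j in range(2)) for y in Y
        )
        assert loss_choice2(Y, R) == pytest.approx(expected, abs=1e-12)

    def test_choice2_bounds(self, rng):
        Y = rng.normal(size=(8, 25))
        R = rng.normal(size=(25, 12))
        L = loss_choice2(Y, R)
        assert -8.0 <= L <= 0.0


class TestGradients:
    @pytest.mark.parametrize(
        "loss,grad",
        [(loss_choice2, grad_loss_choice2), (loss_choice1, grad_loss_choice1)],
        ids=["max-abs-corr", "glm-fit-corr"],
    )
    def test_analytic_gradient_matches_finite_differences(self, rng, loss, grad):
        Y = rng.normal(size=(6, 30))
        R = rng.normal(size=(30, 12))
        l0, g = grad(Y, R)
        assert l0 == pytest.approx(loss(Y, R), abs=1e-12)
        eps = 1e-6
        for _ in range(25):
            i, j = rng.integers(30), rng.integers(12)
            Rp, Rm = R.copy(), R.copy()
            Rp[i, j] += eps
            Rm[i, j] -= eps
            num = (loss(Y, Rp) - loss(Y, Rm)) / (2 * eps)
            assert g[i, j] == pytest.approx(num, abs=5e-5)


class TestInit:
    def test_deterministic(self):
        a, b = init_params(42), init_params(42)
        assert np.array_equal(a.layer1_weights, b.layer1_weights)
        assert np.array_equal(a.layer2_weights, b.layer2_weights)

    def test_xavier_bounds(self):
        p = init_params(5)
        b1 = np.sqrt(6.0 / (5 * 6 + 5 * 32))
        b2 = np.sqrt(6.0 / (5 * 32 + 5 * 12))
        assert np.abs(p.layer1_weights).max() <= b1
        assert np.abs(p.layer2_weights).max() <= b2
        assert not p.layer1_bias.any() and not p.layer2_bias.any()

    def test_parameter_count(self):
        assert init_params(0).n_parameters() == 2924


class TestTraining:
    def test_validation_loss_improves(self, trained):
        h = trained.history
        assert h.val_loss.iloc[-1] < h.val_loss.iloc[0]

    def test_epoch_budget(self, trained):
        assert trained.epochs_run <= 40

    def test_output_shape_and_labels(self, trained, subject):
        assert trained.regressors.values.shape == (subject.data.n_volumes, 12)
        assert trained.regressors.labels == REGRESSOR_LABELS

    def test_deterministic_given_seed(self, subject):
        cfg = TrainConfig(seed=3, max_epochs=2)
        Y = subject.data.non_gm()[:600]
        a = train(subject.motion, Y, cfg)
        b = train(subject.motion, Y, cfg)
        assert np.array_equal(a.regressors.values, b.regressors.values)

    def test_derived_regressors_lie_in_lagged_motion_span(self, trained, subject):
        """With linear activation the output is a lag +/-4 filter of the
        (z-scored) motion channels plus a constant offset; interior time
        points must project onto that 54-series basis exactly."""
        Mz = standardize_columns(subject.motion)
        basis = np.column_stack(
            [_shifted(Mz, j) for j in range(-4, 5)] + [np.ones((len(Mz), 1))]
        )
        R = trained.regressors.values
        interior = slice(4, -4)
        B = basis[interior]
        proj = B @ np.linalg.lstsq(B, R[interior], rcond=None)[0]
        resid = np.abs(R[interior] - proj).max()
        assert resid < 1e-6

    def test_too_few_voxels_raises(self, subject):
        with pytest.raises(ValueError, match="at least 10"):
            train(subject.motion, subject.data.data[:5])

    def test_relu_rejected(self):
        with pytest.raises(ValueError, match="ReLU"):
            TrainConfig(activation="relu")

    def test_sigmoid_activation_trains(self, subject):
        cfg = TrainConfig(seed=1, max_epochs=2, activation="sigmoid")
        model = train(subject.motion, subject.data.non_gm()[:600], cfg)
        assert np.isfinite(model.history.val_loss).all()
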