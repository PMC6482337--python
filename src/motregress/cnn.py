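"""Two-layer temporal CNN deriving subject-specific motion regressors.

The network maps the ``(T, 6)`` realignment parameters through two 1-D
convolutional layers (filter size 5, stride 1, *same* zero padding, 32
then 12 filters, linear activation by default) to a ``(T, 12)`` matrix of
derived regressors. Because the six input channels are shared by every
voxel, the motion input is conceptually replicated across the voxels of a
batch: the forward pass is computed once, and the batch loss couples the
single shared output to each voxel's time series.

Two loss choices are provided, both summed over the batch with a minus
sign so that minimisation drives the regressors toward the voxel series:

* choice 1 — the correlation between each voxel series and its GLM fit on
  the 12 regressors (a multiple-correlation coefficient);
* choice 2 — the largest absolute single-regressor correlation per voxel
  (cheaper, no pseudoinverse per step; the default).

Training uses Adam with a step-count learning-rate decay
``lr_t = eta / (1 + gamma * t)``, Xavier-uniform initial weights, a seeded
90/10 voxel split, and early stopping on the validation loss. Gradients
are computed analytically (and are checked against finite differences in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NumericalFailureError
from .regressors import RegressorSet

FILTER_SIZE = 5
N_INPUT_CHANNELS = 6
N_HIDDEN = 32
N_OUTPUT = 12

#: variance below which a series is treated as constant in correlations
_VAR_GUARD = 1e-12


@dataclass
class NetworkParams:
    """Weights and biases of the two convolutional layers."""

    layer1_weights: np.ndarray  # (5, 6, 32)
    layer1_bias: np.ndarray     # (32,)
    layer2_weights: np.ndarray  # (5, 32, 12)
    layer2_bias: np.ndarray     # (12,)

    def n_parameters(self) -> int:
        return (
            self.layer1_weights.size
            + self.layer1_bias.size
            + self.layer2_weights.size
            + self.layer2_bias.size
        )

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.layer1_weights.copy(),
            self.layer1_bias.copy(),
            self.layer2_weights.copy(),
            self.layer2_bias.copy(),
        )


@dataclass
class TrainConfig:
    """Hyper-parameters of the training loop."""

    batch_size: int = 500
    learning_rate: float = 0.01
    lr_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 40
    val_fraction: float = 0.10
    patience: int = 5
    tol: float = 1e-4
    loss_choice: int = 2
    activation: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_choice not in (1, 2):
            raise ValueError("loss_choice must be 1 or 2")
        if self.activation == "relu":
            raise ValueError(
                "ReLU is not supported: it destabilises this loss "
                "numerically; use 'linear' (default) or 'sigmoid'"
            )
        if self.activation not in ("linear", "sigmoid"):
            raise ValueError("activation must be 'linear' or 'sigmoid'")


@dataclass
class TrainedModel:
    """Result of :func:`train`."""

    params: NetworkParams
    regressors: RegressorSet
    history: pd.DataFrame          # epoch, train_loss, val_loss
    epochs_run: int
    config: TrainConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# forward pass


def _shifted(X: np.ndarray, j: int) -> np.ndarray:
    """Rows ``t`` of the result equal ``X[t + j]``, zero outside [0, T)."""
    out = np.zeros_like(X)
    if j == 0:
        return X.copy()
    if j > 0:
        out[:-j] = X[j:]
    else:
        out[-j:] = X[:j]
    return out


def conv1d_same(X: np.ndarray, filters: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Temporal convolution with stride 1 and zero *same* padding.

    ``X`` is ``(T, C)``, ``filters`` is ``(f, C, F)`` with odd ``f``,
    ``bias`` is ``(F,)``; the output is ``(T, F)`` with
    ``out[t, f] = bias_f + sum_k sum_c X[t + k - f//2, c] W[k, c, f]``.
    """
    X = np.asarray(X, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (T, C) matrix")
    f, C, F = filters.shape
    if f % 2 == 0:
        raise ValueError("filter temporal size must be odd")
    if X.shape[1] != C:
        raise ValueError(
            f"channel mismatch: X has {X.shape[1]} channels, filters expect {C}"
        )
    half = f // 2
    out = np.broadcast_to(np.asarray(bias, dtype=float), (X.shape[0], F)).copy()
    for k in range(f):
        out += _shifted(X, k - half) @ filters[k]
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def forward(
    M: np.ndarray, params: NetworkParams, activation: str = "linear"
) -> np.ndarray:
    """Map ``(T, 6)`` motion parameters to the ``(T, 12)`` regressors."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != N_INPUT_CHANNELS:
        raise ValueError("motion input must be a (T, 6) matrix")
    z = conv1d_same(M, params.layer1_weights, params.layer1_bias)
    if activation == "sigmoid":
        z = _sigmoid(z)
    out = conv1d_same(z, params.layer2_weights, params.layer2_bias)
    if activation == "sigmoid":
        out = _sigmoid(out)
    return out


def composite_filter(params: NetworkParams) -> tuple:
    """Collapse the two linear layers into one 9-tap filter bank.

    Returns ``(K, offsets)`` with ``K`` of shape ``(9, 6, 12)`` and
    ``offsets`` of shape ``(12,)`` such that, away from the edges (where
    the interior zero padding of the hidden layer plays no role),
    ``forward(M)[t] = offsets + sum_m M[t + m - 4] @ K[m]``. Valid for the
    linear activation only.
    """
    W1, W2 = params.layer1_weights, params.layer2_weights
    f = FILTER_SIZE
    K = np.zeros((2 * f - 1, W1.shape[1], W2.shape[2]))
    for k1 in range(f):
        for k2 in range(f):
            K[k1 + k2] += W1[k2] @ W2[k1]
    offsets = params.layer2_bias + np.einsum(
        "c,kcf->f", params.layer1_bias, W2
    )
    return K, offsets


# ---------------------------------------------------------------------------
# losses and gradients


def guarded_correlation(y: np.ndarray, x: np.ndarray) -> float:
    """Pearson correlation, returning 0 for (near-)constant input."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape != x.shape or y.size < 2:
        raise ValueError("series must have equal length >= 2")
    yc = y - y.mean()
    xc = x - x.mean()
    vy = yc @ yc / y.size
    vx = xc @ xc / x.size
    if vy < _VAR_GUARD or vx < _VAR_GUARD:
        return 0.0
    return float(yc @ xc / np.sqrt((yc @ yc) * (xc @ xc)))


def _center_cols(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0)


def loss_choice1(Y: np.ndarray, Rtil: np.ndarray) -> float:
    """Minus the sum of multiple-correlation coefficients.

    Each voxel series is fit by the GLM ``yhat = Rtil Rtil^+ y`` and the
    Pearson correlation between the series and its fit is accumulated.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Rp = np.linalg.pinv(Rtil)
    Yhat = (Rtil @ (Rp @ Y.T)).T
    return -sum(
        guarded_correlation(y, yh) for y, yh in zip(Y, Yhat)
    )


def loss_choice2(Y: np.ndarray, Rtil: np.ndarray) -> float:
    """Minus the sum over voxels of the maximal absolute correlation with
    any single derived regressor."""
    r = _abs_corr_matrix(np.atleast_2d(np.asarray(Y, dtype=float)), Rtil)
    return -float(np.abs(r).max(axis=1).sum())


def _abs_corr_matrix(Y: np.ndarray, Rtil: np.ndarray) -> np.ndarray:
    """Signed correlation matrix (voxels x regressors) with guard rows and
    columns set to zero."""
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Rc = _center_cols(Rtil)
    ny = np.sqrt((Yc**2).sum(axis=1))
    nr = np.sqrt((Rc**2).sum(axis=0))
    T = Y.shape[1]
    good_y = (ny**2 / T) >= _VAR_GUARD
    good_r = (nr**2 / T) >= _VAR_GUARD
    denom = np.outer(np.where(good_y, ny, 1.0), np.where(good_r, nr, 1.0))
    r = (Yc @ Rc) / denom
    r[~good_y, :] = 0.0
    r[:, ~good_r] = 0.0
    return r


def grad_loss_choice2(Y: np.ndarray, Rtil: np.ndarray) -> tuple:
    """Loss value and its gradient with respect to ``Rtil``.

    Only the argmax regressor of each voxel receives gradient (first index
    on ties — the subgradient convention).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    T = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Rc = _center_cols(Rtil)
    ny = np.sqrt((Yc**2).sum(axis=1))
    nr = np.sqrt((Rc**2).sum(axis=0))
    good_y = (ny**2 / T) >= _VAR_GUARD
    good_r = (nr**2 / T) >= _VAR_GUARD
    denom = np.outer(np.where(good_y, ny, 1.0), np.where(good_r, nr, 1.0))
    r = (Yc @ Rc) / denom
    r[~good_y, :] = 0.0
    r[:, ~good_r] = 0.0

    jstar = np.argmax(np.abs(r), axis=1)
    rows = np.arange(Y.shape[0])
    rbest = r[rows, jstar]
    loss = -float(np.abs(rbest).sum())

    sign = np.sign(rbest)
    grad = np.zeros_like(Rtil)
    active = good_y & (np.abs(rbest) > 0)
    for j in range(Rtil.shape[1]):
        if not good_r[j]:
            continue
        sel = active & (jstar == j)
        if not sel.any():
            continue
        s = sign[sel][:, None]
        # d corr(y, x)/dx = C [ y_c/(|y||x|) - r x_c/|x|^2 ]
        term = (s * Yc[sel] / (ny[sel][:, None] * nr[j])).sum(axis=0)
        term -= (s.ravel() * r[sel, j]).sum() * Rc[:, j] / nr[j] ** 2
        grad[:, j] = -(term - term.mean())
    return loss, grad


def grad_loss_choice1(Y: np.ndarray, Rtil: np.ndarray) -> tuple:
    """Loss value and gradient of the GLM-fit correlation loss.

    Uses the projector differential
    ``dP = (I - P) dR R^+ + (R^+)' dR' (I - P)`` for the orthogonal
    projector ``P = R R^+`` onto the regressor column space.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, T = Y.shape
    Rp = np.linalg.pinv(Rtil)            # (12, T)
    B = Rp @ Y.T                         # (12, n) GLM coefficients
    Yhat = Rtil @ B                      # (T, n)
    Yt = Y.T                             # (T, n)

    A = Yt - Yt.mean(axis=0)             # centred voxel series
    Bc = Yhat - Yhat.mean(axis=0)        # centred fits
    na = np.sqrt((A**2).sum(axis=0))
    nb = np.sqrt((Bc**2).sum(axis=0))
    good = ((na**2 / T) >= _VAR_GUARD) & ((nb**2 / T) >= _VAR_GUARD)
    na_s = np.where(good, na, 1.0)
    nb_s = np.where(good, nb, 1.0)
    rvec = np.where(good, (A * Bc).sum(axis=0) / (na_s * nb_s), 0.0)
    loss = -float(rvec.sum())

    # dr/d yhat (per voxel), centred afterwards
    G = A / (na_s * nb_s) - Bc * (rvec / nb_s**2)
    G -= G.mean(axis=0)
    G[:, ~good] = 0.0

    # dL/dR = -[ (I-P) G B' + (I-P) Y (R^+ G)' ]
    PG = Rtil @ (Rp @ G)
    MP_G = G - PG                        # (I - P) G
    PY = Rtil @ B
    MP_Y = Yt - PY                       # (I - P) Y
    grad = -(MP_G @ B.T + MP_Y @ (Rp @ G).T)
    return loss, grad


# ---------------------------------------------------------------------------
# initialisation and training


def init_params(seed: int) -> NetworkParams:
    """Xavier-uniform weights (fan counts include the temporal extent of
    the filters, as in common 1-D convolution implementations) and zero
    biases; deterministic given the seed."""
    rng = np.random.default_rng(seed)

    def xavier(shape):
        f, cin, cout = shape
        bound = np.sqrt(6.0 / (f * cin + f * cout))
        return rng.uniform(-bound, bound, size=shape)

    return NetworkParams(
        layer1_weights=xavier((FILTER_SIZE, N_INPUT_CHANNELS, N_HIDDEN)),
        layer1_bias=np.zeros(N_HIDDEN),
        layer2_weights=xavier((FILTER_SIZE, N_HIDDEN, N_OUTPUT)),
        layer2_bias=np.zeros(N_OUTPUT),
    )


def _conv_backward(X, filters, dOut):
    """Gradients of conv1d_same w.r.t. filters, bias and input."""
    f = filters.shape[0]
    half = f // 2
    dW = np.empty_like(filters)
    for k in range(f):
        dW[k] = _shifted(X, k - half).T @ dOut
    db = dOut.sum(axis=0)
    dX = np.zeros_like(X)
    for k in range(f):
        dX += _shifted(dOut, -(k - half)) @ filters[k].T
    return dW, db, dX


def _forward_cached(Mz, params, activation):
    z1 = conv1d_same(Mz, params.layer1_weights, params.layer1_bias)
    a1 = _sigmoid(z1) if activation == "sigmoid" else z1
    z2 = conv1d_same(a1, params.layer2_weights, params.layer2_bias)
    a2 = _sigmoid(z2) if activation == "sigmoid" else z2
    return z1, a1, z2, a2


def _backward(Mz, params, cache, dRtil, activation):
    z1, a1, z2, a2 = cache
    if activation == "sigmoid":
        dRtil = dRtil * a2 * (1.0 - a2)
    dW2, db2, dA1 = _conv_backward(a1, params.layer2_weights, dRtil)
    if activation == "sigmoid":
        dA1 = dA1 * a1 * (1.0 - a1)
    dW1, db1, _ = _conv_backward(Mz, params.layer1_weights, dA1)
    return dW1, db1, dW2, db2


def standardize_columns(M: np.ndarray) -> np.ndarray:
    """Z-score each motion channel; zero-variance channels stay zero."""
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (M - mu) / sd_safe


class _Adam:
    """Adam with the legacy step-count learning-rate decay
    ``lr_t = lr / (1 + decay * t)``."""

    def __init__(self, shapes, cfg: TrainConfig):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.cfg = cfg

    def step(self, params_list, grads):
        cfg = self.cfg
        self.t += 1
        lr = cfg.learning_rate / (1.0 + cfg.lr_decay * self.t)
        for p, g, m, v in zip(params_list, grads, self.m, self.v):
            m *= cfg.beta1
            m += (1 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1 - cfg.beta2) * g**2
            mhat = m / (1 - cfg.beta1**self.t)
            vhat = v / (1 - cfg.beta2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + 1e-8)


REGRESSOR_LABELS = tuple(f"cnn{i + 1:02d}" for i in range(N_OUTPUT))


def train(
    M: np.ndarray, nonGM: np.ndarray, config: TrainConfig | None = None
) -> TrainedModel:
    """Fit the network on non-GM voxel series and return the regressors.

    The motion input is z-scored per channel; voxels are split 90/10 into
    training and validation sets; each epoch shuffles the training voxels
    into batches (the final partial batch is kept) whose summed loss is
    backpropagated through the shared forward pass. The validation loss is
    tracked as the per-voxel mean, and training stops once it has failed
    to improve by ``tol`` for ``patience`` consecutive epochs, or at
    ``max_epochs``.
    """
    config = config or TrainConfig()
    M = np.asarray(M, dtype=float)
    nonGM = np.asarray(nonGM, dtype=float)
    if nonGM.ndim != 2 or nonGM.shape[0] < 10:
        raise ValueError("need at least 10 non-GM voxel series to train")
    T = M.shape[0]
    if nonGM.shape[1] != T:
        raise ValueError("voxel series length must match motion rows")
    if T < 2 * FILTER_SIZE - 1:
        raise ValueError("need at least 9 time points")

    rng = np.random.default_rng(config.seed)
    Mz = standardize_columns(M)
    params = init_params(int(rng.integers(2**31)))

    V = nonGM.shape[0]
    perm = rng.permutation(V)
    n_val = max(1, int(round(config.val_fraction * V)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Y_val = nonGM[val_idx]

    loss_and_grad = grad_loss_choice2 if config.loss_choice == 2 else grad_loss_choice1
    loss_fn = loss_choice2 if config.loss_choice == 2 else loss_choice1

    plist = [
        params.layer1_weights,
        params.layer1_bias,
        params.layer2_weights,
        params.layer2_bias,
    ]
    opt = _Adam([p.shape for p in plist], config)

    history = []
    best_val = np.inf
    stall = 0
    epochs_run = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(train_idx)
        train_loss_total = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = nonGM[order[start:start + config.batch_size]]
            cache = _forward_cached(Mz, params, config.activation)
            loss, dRtil = loss_and_grad(batch, cache[3])
            if not np.isfinite(loss):
                raise NumericalFailureError(
                    f"non-finite training loss at epoch {epoch}"
                )
            train_loss_total += loss
            grads = _backward(Mz, params, cache, dRtil, config.activation)
            opt.step(plist, grads)
        Rtil = forward(Mz, params, config.activation)
        val_loss = loss_fn(Y_val, Rtil) / len(val_idx)
        if not np.isfinite(val_loss):
            raise NumericalFailureError(
                f"non-finite validation loss at epoch {epoch}"
            )
        history.append(
            (epoch, train_loss_total / max(len(train_idx), 1), val_loss)
        )
        epochs_run = epoch
        if best_val - val_loss > config.tol:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    regressors = RegressorSet(
        forward(Mz, params, config.activation), REGRESSOR_LABELS
    )
    return TrainedModel(
        params=params,
        regressors=regressors,
        history=pd.DataFrame(
            history, columns=["epoch", "train_loss", "val_loss"]
        ),
        epochs_run=epochs_run,
        config=config,
    )
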