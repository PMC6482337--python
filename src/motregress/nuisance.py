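"""Voxel-wise least-squares nuisance regression and variance bookkeeping.

Regression is ordinary least squares via the pseudoinverse, always with an
implicit intercept: voxel series and regressor columns are demeaned before
projection, so ``residuals + fitted + per-voxel mean`` reconstructs the
input exactly and rank deficiency is tolerated. Variance fractions use the
population convention (divide by T) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .regressors import RegressorSet


@dataclass
class RegressionResult:
    """Residuals, fitted motion contribution and per-voxel variance ratio."""

    residuals: np.ndarray                 # (V, T)
    fitted: np.ndarray                    # (V, T), intercept excluded
    voxel_means: np.ndarray               # (V,)
    remaining_variance_fraction: np.ndarray  # (V,) in [0, 1]

    def reconstruct(self) -> np.ndarray:
        return self.residuals + self.fitted + self.voxel_means[:, None]


def linear_detrend(Y: np.ndarray) -> np.ndarray:
    """Remove each row's least-squares line over time (mean and trend)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 3:
        raise ValueError("need a (V, T) matrix with T >= 3")
    T = Y.shape[1]
    t = np.arange(T, dtype=float)
    t -= t.mean()
    slope = (Y @ t) / (t @ t)
    return Y - Y.mean(axis=1, keepdims=True) - slope[:, None] * t


def _design_pinv(values: np.ndarray) -> tuple:
    """Demeaned design matrix and its pseudoinverse with a scaled cutoff."""
    Xc = values - values.mean(axis=0)
    T, K = Xc.shape
    # cutoff relative to the largest singular value, scaled by matrix size
    return Xc, np.linalg.pinv(Xc, rcond=max(T, K) * np.finfo(float).eps)


def regress_out(Y: np.ndarray, rset: RegressorSet) -> RegressionResult:
    """OLS-remove the regressor-explained part of every voxel series."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a (V, T) matrix")
    if rset.n_volumes != Y.shape[1]:
        raise ValueError(
            f"regressor rows ({rset.n_volumes}) do not match data volumes "
            f"({Y.shape[1]})"
        )
    Xc, Xp = _design_pinv(rset.values)
    mu = Y.mean(axis=1)
    Yc = Y - mu[:, None]
    fitted = (Xc @ (Xp @ Yc.T)).T
    residuals = Yc - fitted
    var_orig = Yc.var(axis=1)
    var_res = residuals.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(var_orig > 0, var_res / np.where(var_orig > 0, var_orig, 1.0), 1.0)
    return RegressionResult(
        residuals=residuals,
        fitted=fitted,
        voxel_means=mu,
        remaining_variance_fraction=np.clip(frac, 0.0, 1.0),
    )


def explained_variance_between_sets(
    set1: RegressorSet, set2: RegressorSet
) -> float:
    """Mean R-squared (in %) of set2's columns regressed on set1.

    Each column of ``set2`` is fit by OLS on ``set1`` (with intercept);
    the per-column R^2 values are averaged and returned as a percentage.
    Zero-variance columns in ``set2`` are excluded with a warning.
    """
    if set1.n_volumes != set2.n_volumes:
        raise ValueError("regressor sets must share the number of volumes")
    sd = set2.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [lab for lab, k in zip(set2.labels, keep) if not k]
        warnings.warn(
            f"zero-variance columns excluded from explained-variance "
            f"average: {dropped}",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all columns of set2 are degenerate")
    Xc, Xp = _design_pinv(set1.values)
    Yc = set2.values[:, keep] - set2.values[:, keep].mean(axis=0)
    fitted = Xc @ (Xp @ Yc)
    r2 = (fitted**2).sum(axis=0) / (Yc**2).sum(axis=0)
    return float(100.0 * r2.mean())
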