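"""Traditional motion-regressor families and tissue-mean regressors.

The families follow common nuisance-regression practice for rigid-body
realignment parameters ``R`` (3 translations in mm, 3 rotations in rad):

* ``mot6``  = [R]
* ``mot12`` = [R, R'] with R' the backward temporal derivative
* ``mot24`` = [R, R^2, R_{t-1}, R_{t-1}^2]
* ``mot36`` = [R, R^2, R_{t-1}, R_{t-1}^2, R_{t-2}, R_{t-2}^2]

Shifted copies pad their leading rows with zeros, squares are element-wise
on the raw (uncentered) parameters, and no intercept column belongs to any
family — demeaning is handled inside the regression step. Global-signal
regression is deliberately not provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BoldDataset, CSF, WM, TISSUE_NAMES
from .errors import DegenerateDataError

MOTION_LABELS = ("X", "Y", "Z", "pitch", "yaw", "roll")

FAMILY_SIZES = {"mot6": 6, "mot12": 12, "mot24": 24, "mot36": 36}


@dataclass
class RegressorSet:
    """A ``(T, K)`` matrix of nuisance regressors with column labels."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (T, K) matrix")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    def degenerate_columns(self) -> list:
        """Labels of zero-variance columns (flagged, not removed)."""
        sd = self.values.std(axis=0)
        return [lab for lab, s in zip(self.labels, sd) if s == 0.0]

    def hstack(self, other: "RegressorSet") -> "RegressorSet":
        if other.n_volumes != self.n_volumes:
            raise ValueError("row counts differ")
        return RegressorSet(
            np.hstack([self.values, other.values]), self.labels + other.labels
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=list(self.labels)).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "RegressorSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), tuple(df.columns))


def backward_derivative(M: np.ndarray) -> np.ndarray:
    """Backward temporal difference; the first row is filled with zeros."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 time points for a derivative")
    out = np.zeros_like(M)
    out[1:] = M[1:] - M[:-1]
    return out


def _shift(M: np.ndarray, lag: int) -> np.ndarray:
    """Copy of ``M`` delayed by ``lag`` volumes, leading rows zero."""
    out = np.zeros_like(M)
    out[lag:] = M[:-lag] if lag else M
    return out


def build_regressor_set(M: np.ndarray, family: str) -> RegressorSet:
    """Construct one of the named motion-regressor families from ``(T, 6)``
    realignment parameters."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion parameters must be a (T, 6) matrix")
    if family not in FAMILY_SIZES:
        raise ValueError(
            f"unknown family {family!r}; expected one of {sorted(FAMILY_SIZES)}"
        )
    if family == "mot36" and M.shape[0] < 3:
        raise ValueError("mot36 requires at least 3 time points")

    base = list(MOTION_LABELS)
    blocks = [(M, base)]
    if family == "mot12":
        blocks.append((backward_derivative(M), [f"d{c}" for c in base]))
    elif family in ("mot24", "mot36"):
        lag1 = _shift(M, 1)
        blocks.append((M**2, [f"{c}^2" for c in base]))
        blocks.append((lag1, [f"{c}_t-1" for c in base]))
        blocks.append((lag1**2, [f"{c}_t-1^2" for c in base]))
        if family == "mot36":
            lag2 = _shift(M, 2)
            blocks.append((lag2, [f"{c}_t-2" for c in base]))
            blocks.append((lag2**2, [f"{c}_t-2^2" for c in base]))

    values = np.hstack([b for b, _ in blocks])
    labels = tuple(lab for _, labs in blocks for lab in labs)
    assert values.shape[1] == FAMILY_SIZES[family]
    return RegressorSet(values, labels)


def tissue_mean_regressors(data: BoldDataset) -> RegressorSet:
    """Average WM and CSF series (over eroded-mask voxels) as two regressors."""
    cols, labels = [], []
    for code, label in ((WM, "wm_mean"), (CSF, "csf_mean")):
        sel = data.mask(code)
        if not sel.any():
            raise DegenerateDataError(
                f"no {TISSUE_NAMES[code]} voxels available for the tissue-mean "
                f"regressor (mask empty after erosion?)"
            )
        cols.append(data.data[sel].mean(axis=0))
        labels.append(label)
    return RegressorSet(np.column_stack(cols), tuple(labels))
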