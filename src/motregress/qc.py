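"""Head-motion and data-quality measurements.

Framewise displacement (FD) summarises the realignment-parameter change
between consecutive volumes, with rotations converted to arc length on a
50 mm sphere. rmsFD is the root-mean-square voxel displacement induced by
the relative rigid-body transform between neighbouring volumes, evaluated
over a spherical-shell head model of the same radius. DVARS and mean
whole-brain variance are computed from the image data itself, on
percent-signal-change normalised series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

#: Head radius (mm) used to convert rotations to displacement.
DEFAULT_RADIUS_MM = 50.0

#: Subjects at or above this mean FD (mm) form the high-motion group.
HIGH_MOTION_FD_MM = 0.25


@dataclass
class QCSummary:
    """Per-volume QC traces plus per-subject scalars."""

    fd: np.ndarray
    rmsfd: np.ndarray
    dvars: np.ndarray
    mean_fd: float
    mean_dvars: float
    mean_whole_brain_variance: float
    motion_group: str


def framewise_displacement(
    M: np.ndarray, radius_mm: float = DEFAULT_RADIUS_MM
) -> np.ndarray:
    """Sum of absolute backward differences of the six parameters, with the
    three rotation columns scaled by ``radius_mm``; the first element is 0."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion parameters must be a (T, 6) matrix")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(M, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def _rotations(angles: np.ndarray) -> Rotation:
    # SPM stores pitch/yaw/roll as rotations about x, y, z in radians.
    return Rotation.from_euler("xyz", angles)


def rms_fd(M: np.ndarray, radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """RMS displacement over a spherical shell for each volume transition.

    For the relative transform x -> Q x + d between neighbouring volumes,
    the mean squared displacement over a shell of radius r is
    ``(r^2 / 3) * ||Q - I||_F^2 + ||d||^2`` (the shell has zero mean and
    isotropic second moment ``r^2/3 I``); rmsFD is its square root. A pure
    translation therefore yields its Euclidean norm, and a small rotation
    by theta yields ``r * theta * sqrt(2/3)``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion parameters must be a (T, 6) matrix")
    T = M.shape[0]
    if T < 2:
        raise ValueError("need at least 2 volumes to compute rmsFD")
    rot = _rotations(M[:, 3:]).as_matrix()          # (T, 3, 3)
    trans = M[:, :3]
    out = np.zeros(T)
    eye = np.eye(3)
    for t in range(1, T):
        # relative transform: current o inverse(previous)
        q = rot[t] @ rot[t - 1].T
        d = trans[t] - q @ trans[t - 1]
        out[t] = np.sqrt(
            (radius_mm**2 / 3.0) * np.sum((q - eye) ** 2) + d @ d
        )
    return out


def percent_signal_change(Y: np.ndarray) -> np.ndarray:
    """Per-voxel normalisation ``100 * (x - mean) / mean``.

    Voxels whose temporal mean is not strictly positive cannot be
    normalised; they are returned as all-zero rows with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    mu = Y.mean(axis=1, keepdims=True)
    bad = (mu <= 0).ravel()
    if bad.any():
        warnings.warn(
            f"{bad.sum()} voxel(s) with non-positive temporal mean excluded "
            f"from percent-signal-change conversion",
            stacklevel=2,
        )
    safe = np.where(mu > 0, mu, 1.0)
    out = 100.0 * (Y - mu) / safe
    out[bad] = 0.0
    return out


def dvars(Y: np.ndarray) -> np.ndarray:
    """RMS across voxels of the temporal backward difference at each volume;
    the first element is 0. ``Y`` should be intensity-normalised."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("need a non-empty (V, T) matrix")
    d = np.diff(Y, axis=1)
    return np.concatenate([[0.0], np.sqrt(np.mean(d**2, axis=0))])


def mean_whole_brain_variance(Y: np.ndarray) -> float:
    """Mean over voxels of the temporal (population) variance; ``Y`` should
    already be in percent signal change."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("need a non-empty (V, T) matrix")
    return float(Y.var(axis=1).mean())


def metric_ratio(before: float, after: float) -> float:
    """After/before ratio of a QC measurement around a denoising step."""
    if not before > 0:
        raise ValueError("the before-denoising value must be positive")
    return after / before


def assign_motion_group(mean_fd: float) -> str:
    """'high' iff mean FD >= 0.25 mm (boundary inclusive), else 'low'."""
    if not np.isfinite(mean_fd):
        raise ValueError("mean FD must be finite")
    return "high" if mean_fd >= HIGH_MOTION_FD_MM else "low"


def qc_summary(M: np.ndarray, Y_psc: np.ndarray) -> QCSummary:
    """Bundle all per-volume traces and per-subject scalars.

    ``Y_psc`` must already be percent-signal-change normalised (or
    comparable fluctuation units); mean FD averages over all T elements
    including the leading zero.
    """
    fd = framewise_displacement(M)
    dv = dvars(Y_psc)
    mean_fd = float(fd.mean())
    return QCSummary(
        fd=fd,
        rmsfd=rms_fd(M),
        dvars=dv,
        mean_fd=mean_fd,
        mean_dvars=float(dv.mean()),
        mean_whole_brain_variance=mean_whole_brain_variance(Y_psc),
        motion_group=assign_motion_group(mean_fd),
    )
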