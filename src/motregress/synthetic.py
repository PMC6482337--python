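"""Synthetic motion-corrupted BOLD data with known ground truth.

The generator emulates a single resting-state scan after standard
preprocessing: a ``(T, 6)`` realignment-parameter trace (smooth random
walk plus occasional spikes), and a voxel-by-time matrix in which every
voxel carries a motion-driven artifact — a temporally prolonged,
voxel-varying causal linear response to the six motion channels — plus
white noise, and gray-matter voxels additionally share a handful of
smooth latent "network" signals. The additive decomposition of every
voxel series into artifact, neural and noise components is stored
exactly, so downstream denoising can be scored against ground truth.

Defaults mirror a 3 s-TR acquisition with 140 volumes of which the first
five are discarded (T = 135), roughly 10,000 usable white-matter voxels
after erosion, and an artifact occupying half of the non-neural signal
variance. The artifact kernels are damped smooth random sequences with a
decay of about two volumes (six seconds), a plausible time scale for
spin-history-like prolongation; they are a stand-in family, not an
empirically characterised one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .containers import BoldDataset, CSF, GM, WM
from .errors import DegenerateDataError, InvalidConfigError
from .nuisance import _design_pinv
from .regressors import RegressorSet

#: kernel amplitude decay time constant, in volumes
_KERNEL_DECAY_VOLUMES = 2.0

#: internal seeds of the reference traces used to calibrate artifact scale
_REFERENCE_SEED = 961748927
_N_REFERENCE_TRACES = 4


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic subject."""

    T: int = 135
    n_gm: int = 2000
    n_wm: int = 10000
    n_csf: int = 2000
    spike_rate: float = 2.0          # expected motion spikes per scan
    spike_amplitude_mm: float = 0.8  # typical translation spike size
    drift_sd: float = 0.04           # random-walk step SD, mm
    jitter_sd: float | None = None   # per-volume jitter SD, mm; None -> 0.75*drift_sd
    kernel_len: int = 9              # artifact response length, volumes
    artifact_frac: float = 0.5      # artifact share of non-GM variance
    neural_frac: float = 0.2        # neural share of GM variance
    n_networks: int = 5             # shared latent signals for GM
    spike_channels: str = "translations"   # or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise InvalidConfigError("T must be at least 2")
        if self.T < self.kernel_len:
            raise InvalidConfigError("T must be >= kernel_len")
        if min(self.n_gm, self.n_wm, self.n_csf) <= 0:
            raise InvalidConfigError("all voxel counts must be positive")
        if not 0.0 <= self.artifact_frac <= 1.0:
            raise InvalidConfigError("artifact_frac must lie in [0, 1]")
        if not 0.0 <= self.neural_frac <= 1.0 - 1e-12:
            raise InvalidConfigError("neural_frac must lie in [0, 1)")
        if self.artifact_frac + self.neural_frac > 1.0:
            raise InvalidConfigError("artifact_frac + neural_frac must be <= 1")
        if self.spike_channels not in ("translations", "all"):
            raise InvalidConfigError("spike_channels: 'translations' or 'all'")


@dataclass
class SyntheticGroundTruth:
    """Exact per-voxel additive decomposition of the data."""

    artifact: np.ndarray   # (V, T)
    neural: np.ndarray     # (V, T)
    noise: np.ndarray      # (V, T)
    kernels: np.ndarray = field(repr=False, default=None)  # (V, kernel_len*6)


@dataclass
class SyntheticSubject:
    motion: np.ndarray     # (T, 6)
    data: BoldDataset
    truth: SyntheticGroundTruth
    config: SyntheticConfig


def generate_motion_trace(config: SyntheticConfig) -> np.ndarray:
    """Realignment trace: smooth random walk + per-volume jitter + spikes.

    Translations are in mm; rotation SDs are scaled by 1/50 so a 50 mm
    head radius gives them comparable framewise displacement. The jitter
    term is independent volume-to-volume noise emulating the
    respiration/tremor-scale fluctuations seen in real realignment
    estimates at a 3 s TR — without it, delayed copies of the trace are
    nearly collinear and the lag structure of the artifact would be
    unidentifiable. Spikes are one-volume excursions, added to
    translation channels only by default. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    T = config.T
    step_sd = np.array([config.drift_sd] * 3 + [config.drift_sd / 50.0] * 3)
    steps = rng.normal(0.0, 1.0, size=(T, 6))
    if T >= 5:
        # short moving average keeps the walk smooth without killing the
        # per-step displacement scale
        steps = uniform_filter1d(steps, size=3, axis=0, mode="nearest")
        steps /= max(steps.std(), 1e-12)
    M = np.cumsum(steps * step_sd, axis=0)
    M -= M[0]
    jitter = (0.75 * config.drift_sd if config.jitter_sd is None
              else config.jitter_sd)
    jit_sd = np.array([jitter] * 3 + [jitter / 50.0] * 3)
    M += rng.normal(0.0, 1.0, size=(T, 6)) * jit_sd

    # fixed count at the expected rate (+ Bernoulli remainder) rather than
    # a Poisson draw: keeps the artifact energy budget comparable across
    # subjects while preserving the configured rate in expectation
    whole, rem = divmod(config.spike_rate, 1.0)
    n_spikes = int(whole) + (rng.random() < rem)
    n_chan = 3 if config.spike_channels == "translations" else 6
    for _ in range(n_spikes):
        t = int(rng.integers(1, T))
        c = int(rng.integers(0, n_chan))
        amp = config.spike_amplitude_mm * rng.uniform(0.75, 1.25)
        if c >= 3:
            amp /= 50.0
        M[t, c] += amp * rng.choice([-1.0, 1.0])
    return M


def lagged_motion_basis(M: np.ndarray, kernel_len: int) -> np.ndarray:
    """``(T, kernel_len * 6)`` matrix of causally delayed motion channels;
    column ``k*6 + c`` is channel ``c`` delayed by ``k`` volumes (leading
    rows zero). The true artifact of every voxel lies in its span."""
    T = M.shape[0]
    out = np.zeros((T, kernel_len * M.shape[1]))
    for k in range(kernel_len):
        out[k:, k * M.shape[1]:(k + 1) * M.shape[1]] = M[:T - k]
    return out


#: number of shared temporal kernel profiles per subject
_N_KERNEL_PROFILES = 2


def _draw_kernels(rng, n_voxels: int, kernel_len: int, n_chan: int) -> np.ndarray:
    """Smooth damped random causal kernels, one per voxel and channel.

    Each voxel/channel kernel is a random combination of a small number
    of smooth damped temporal profiles shared across the subject,
    emulating spin-history-like responses with a common time course but
    voxel-varying amplitude and sign. The shared profiles make the
    artifact subspace ``n_chan * n_profiles``-dimensional (12 for six
    motion channels), so a 12-regressor set can in principle span it.
    The profiles sum to zero: a head held in a fixed (if displaced)
    position disturbs the steady-state signal only while it moves, so
    the response is to motion *change*, not absolute position.
    """
    profiles = rng.normal(size=(_N_KERNEL_PROFILES, kernel_len))
    profiles = uniform_filter1d(profiles, size=3, axis=1, mode="nearest")
    profiles *= np.exp(-np.arange(kernel_len) / _KERNEL_DECAY_VOLUMES)
    profiles -= profiles.mean(axis=1, keepdims=True)
    profiles /= np.linalg.norm(profiles, axis=1, keepdims=True)
    coef = rng.normal(size=(n_voxels, n_chan, _N_KERNEL_PROFILES))
    h = np.einsum("vcp,pk->vkc", coef, profiles)
    return h.reshape(n_voxels, kernel_len * n_chan)


def _scale_rows(X: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale each row to the target population variance; zero-variance
    rows are left untouched."""
    sd = X.std(axis=1, keepdims=True)
    scale = np.where(sd > 0, np.sqrt(target_var) / np.where(sd > 0, sd, 1.0), 0.0)
    return X * scale


def synthesize_subject(config: SyntheticConfig) -> SyntheticSubject:
    """Generate one complete synthetic subject.

    Per voxel the series is ``artifact + neural + noise`` exactly; the
    total variance is 1 by construction, with the artifact scaled to
    ``artifact_frac`` (times ``1 - neural_frac`` for GM, keeping the
    artifact/noise proportion equal across tissues) and, for GM voxels,
    the shared latent signals scaled to ``neural_frac``.
    """
    motion = generate_motion_trace(config)
    rng = np.random.default_rng([config.seed, 1])
    T = config.T
    V = config.n_gm + config.n_wm + config.n_csf
    tissue = np.concatenate([
        np.full(config.n_gm, GM),
        np.full(config.n_wm, WM),
        np.full(config.n_csf, CSF),
    ])
    is_gm = tissue == GM

    basis = lagged_motion_basis(motion, config.kernel_len)
    if config.artifact_frac > 0 and not basis.any():
        if config.artifact_frac >= 1.0:
            raise DegenerateDataError(
                "artifact_frac = 1 with a zero motion trace: no artifact "
                "can be generated"
            )
    kernels = _draw_kernels(rng, V, config.kernel_len, 6)
    # Calibrate each voxel's kernel against a fixed-seed *reference* trace
    # drawn from the same config, so that the artifact fraction is the
    # target in expectation while the realized motion energy of THIS trace
    # still passes through to the data: higher-motion subjects carry
    # proportionally more artifact variance, as real cohorts do.
    ref_var = np.zeros(V)
    for k in range(_N_REFERENCE_TRACES):
        ref = generate_motion_trace(replace(config, seed=_REFERENCE_SEED + k))
        ref_var += (kernels @ lagged_motion_basis(ref, config.kernel_len).T).var(axis=1)
    ref_var /= _N_REFERENCE_TRACES
    af = np.where(is_gm, config.artifact_frac * (1.0 - config.neural_frac),
                  config.artifact_frac)
    scale = np.where(ref_var > 0, np.sqrt(af) / np.sqrt(np.where(ref_var > 0, ref_var, 1.0)), 0.0)
    kernels = kernels * scale[:, None]
    artifact = kernels @ basis.T                      # (V, T)
    if config.artifact_frac == 0:
        artifact = np.zeros((V, T))
        kernels = np.zeros_like(kernels)

    neural = np.zeros((V, T))
    if config.n_networks > 0 and config.neural_frac > 0:
        latents = rng.normal(size=(config.n_networks, T))
        latents = gaussian_filter1d(latents, sigma=2.0, axis=1, mode="nearest")
        weights = rng.normal(size=(config.n_gm, config.n_networks))
        neural[is_gm] = _scale_rows(weights @ latents, config.neural_frac)

    noise_var = np.maximum(1.0 - af - np.where(is_gm, config.neural_frac, 0.0), 0.0)
    noise = rng.normal(size=(V, T)) * np.sqrt(noise_var)[:, None]

    data = artifact + neural + noise

    from .io import slab_layout
    indices, _ = slab_layout(tissue)
    coords = indices * 3.0    # 3 mm isotropic grid

    return SyntheticSubject(
        motion=motion,
        data=BoldDataset(data=data, tissue=tissue, coords=coords),
        truth=SyntheticGroundTruth(
            artifact=artifact, neural=neural, noise=noise, kernels=kernels
        ),
        config=config,
    )


def artifact_variance_explained(
    subject: SyntheticSubject, regressors: RegressorSet
) -> float:
    """Fraction of true non-GM artifact variance inside the regressor span.

    For every WM/CSF voxel with a non-degenerate artifact component, the
    component is projected (with intercept) onto the regressor column
    space; the per-voxel ratio of projected to total artifact variance is
    averaged. This is the ground-truth analogue of comparing remaining
    variance after nuisance regression.
    """
    if regressors.n_volumes != subject.data.n_volumes:
        raise ValueError("regressor rows must match the subject's volumes")
    nongm = subject.data.mask(WM, CSF)
    A = subject.truth.artifact[nongm]
    var_a = A.var(axis=1)
    keep = var_a > 1e-15
    if not keep.any():
        raise DegenerateDataError(
            "all non-GM voxels have a zero-variance artifact component"
        )
    Ac = A[keep] - A[keep].mean(axis=1, keepdims=True)
    Xc, Xp = _design_pinv(regressors.values)
    proj = (Xc @ (Xp @ Ac.T)).T
    return float((proj.var(axis=1) / var_a[keep]).mean())
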