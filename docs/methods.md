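# Methods

## The denoising model

Nuisance regression removes, voxel by voxel, the part of a BOLD time
series that lies in the column space of a regressor matrix. The package's
core contribution is how that matrix is built: a two-layer temporal CNN
maps the `(T, 6)` rigid-body realignment parameters (translations in mm,
rotations in radians, SPM column order) to `(T, 12)` derived regressors.

Both layers are 1-D convolutions along time with filter size 5, stride 1
and zero *same* padding (32 filters, then 12), linear activation, for
5·6·32 + 32 + 5·32·12 + 12 = 2,924 parameters. With linear activation the
network is, away from the padded edges, exactly a 9-tap linear filter
bank on the motion channels (`composite_filter` computes it, and the test
suite uses it as an algebraic oracle), so each derived regressor is a
learned lag ±4 filtering of motion — the model class that motivates the
approach: motion artifacts are prolonged and voxel-varying, and the
instantaneous families `[R]`, `[R, R']`, … are low-dimensional special
cases of it.

Training pairs the single shared forward output with each voxel series of
a batch (the "replication" construction: the motion input is conceptually
copied once per voxel, so thousands of WM/CSF series become samples).
Only non-gray-matter voxels are used, on the assumption that they carry
motion artifact but no neural signal; this keeps the regressors from
modeling the signal of interest. The loss over a batch of n voxels is a
minus sum of per-voxel correlations, in two variants:

* **choice 2 (default)** — the largest absolute Pearson correlation
  between the voxel series and any single derived regressor. Cheap: no
  pseudoinverse per step.
* **choice 1** — the correlation between the voxel series and its GLM fit
  on all 12 regressors (a multiple-correlation coefficient); the
  pseudoinverse is recomputed at every update.

Gradients for both are analytic (the choice-1 gradient goes through the
differential of the orthogonal projector, `dP = (I−P) dR R⁺ + (R⁺)ᵀ dRᵀ
(I−P)`); both are verified against central finite differences in the
tests. Ties in the argmax of choice 2 take the first index — a
measure-zero subgradient convention. Correlations are guarded: a series
with variance below 1e-12 correlates to 0 by definition.

## Optimization choices

* Adam with β₁ = 0.9, β₂ = 0.999, bias correction, ε = 1e-8, and the
  legacy step-count decay `lr_t = 0.01 / (1 + 0.05·t)` over batch updates
  (the dialect of "learning-rate decay" used by the framework generation
  this architecture comes from). Exposed in `TrainConfig`.
* Xavier-uniform initialization with fan counts including the temporal
  extent (`bound = sqrt(6 / (5·C_in + 5·C_out))`); biases start at zero.
* Motion channels are z-scored before entering the network, for
  conditioning only — least-squares removal is invariant to regressor
  scaling. Zero-variance channels pass through as zeros.
* Voxels split 90/10 into train/validation; each epoch shuffles training
  voxels into batches of 500, keeping the final partial batch. The batch
  loss is a sum (not mean) over voxels, so the last partial batch carries
  a proportionally smaller gradient — accepted as part of the definition.
* Early stopping monitors the **per-voxel mean** validation loss: stop
  when it has failed to improve by `tol = 1e-4` for `patience = 5`
  consecutive epochs, hard cap 40 epochs. The per-voxel scale is the one
  on which a 1e-4 tolerance is meaningful (a summed loss over ~1,000
  validation voxels would never trigger it). In practice, with the
  decayed learning rate the validation loss keeps creeping by about the
  tolerance per epoch, so full-size fits typically use the whole 40-epoch
  budget while being visibly flat over the last half.
* Activations: linear (default) and sigmoid. ReLU is rejected with an
  explanatory error — a max-of-absolute-correlations loss on top of
  half-dead linear outputs destabilizes training.
* One integer seed drives initialization, the voxel split and batch
  shuffling; identical seeds give bit-identical regressors.

## Traditional families and regression

`mot6 = [R]`, `mot12 = [R, R']`, `mot24 = [R, R², R_{t−1}, R_{t−1}²]`,
`mot36 = [… R_{t−2}, R_{t−2}²]`. Backward differences and lags zero-fill
their leading rows; squares apply to the raw (uncentered) parameters. No
family contains an intercept: `regress_out` always demeans series and
regressors internally, which is equivalent to an explicit intercept and
guarantees `residuals + fitted + voxel mean` reconstructs the input
exactly. Variance fractions use the population convention (divide by T).
The pseudoinverse cutoff is `max(T, K)·eps` relative to the largest
singular value, so rank-deficient sets (e.g. all-zero motion) are
tolerated. A documented nuance: `[R, R']` and `[R, R_{t−1}]` span the
same columns only for t ≥ 2 — the zero-filled first rows of a derivative
and of a lag differ — and the property tests respect that. Global-signal
regression is intentionally absent.

## QC metrics

* **FD**: sum of absolute backward differences of the six parameters,
  rotations × 50 mm; first element 0; the per-subject mean averages over
  all T elements including that 0. Subjects with mean FD ≥ 0.25 mm form
  the high-motion group (boundary inclusive).
* **rmsFD**: for the relative rigid transform `x → Qx + d` between
  neighbouring volumes, the RMS displacement over a 50 mm spherical
  shell, which has the closed form `sqrt((r²/3)·‖Q−I‖_F² + ‖d‖²)`
  (zero mean and isotropic second moment r²/3 on the shell). Pure
  translations give their norm; a small rotation θ gives
  `r·θ·sqrt(2/3)`, which the tests check against a Monte-Carlo shell
  average. The precise formula behind the published measurement is not
  fully specified anywhere accessible, so this spherical-shell model is
  the package's documented convention, validated through its limit cases.
* **DVARS**: RMS across voxels of the temporal backward difference, on
  percent-signal-change data (`100·(x−mean)/mean`; voxels with
  non-positive means are excluded with a warning). **Mean whole-brain
  variance**: mean over voxels of the temporal variance of the psc data.
  Both are reported before/after regression as ratios (after/before).

## Connectivity evaluation

ROI series are unweighted voxel means over atlas labels; FC is guarded
Pearson correlation with unit diagonal. Distance dependence fits an OLS
line (with a t-based 95% CI on the slope) of upper-triangle FC — or of
Δr = FC_after − FC_before — against pairwise Euclidean ROI-center
distance. Modularity Q is maximized by Louvain (networkx implementation)
over seeded restarts, best-of-`runs` returned; negative FC weights are
zeroed by default (absolute value available), resolution exposed. r is
used directly, without Fisher transform. ROI centers are unweighted mean
member-voxel coordinates in mm.

## Mask erosion

6-connectivity binary erosion. The CSF mask is eroded once; the WM mask
is eroded repeatedly but never below 10,000 voxels — interpreted as "the
maximal number of erosions keeping at least 10,000 voxels", so a mask
whose first erosion would cross the floor is returned unchanged. In the
pipeline, a CSF mask that a single erosion would empty (possible on small
synthetic slabs) is kept un-eroded with a warning. A literal
`iterations=k` override is available.

## The synthetic generator

The generator emulates a post-preprocessing single-subject scan at a 3 s
TR: 135 retained volumes, ~12,000 usable WM/CSF voxels, unit-variance
voxel series. Its components, and what they stand for:

* **Motion trace**: a smooth random walk (slow drift; step SD 0.04 mm,
  rotations scaled by 1/50) plus independent per-volume jitter (default
  0.75 × drift SD) plus sparse one-volume spikes (2 per scan at ~0.8 mm
  on a random translation channel). The jitter matters structurally, not
  just cosmetically: without it, delayed copies of the trace are almost
  collinear and *every* regressor family trivially spans any lagged
  artifact — no method could be distinguished from any other. The spike
  count is fixed at the expected rate (with a Bernoulli remainder for
  non-integer rates) so the artifact energy budget is comparable across
  subjects.
* **Artifact**: per voxel, a causal length-9 kernel response summed over
  the six motion channels. Kernels are random combinations of two smooth,
  exponentially damped (≈2-volume decay) temporal profiles shared across
  the subject — emulating spin-history-like responses with a common time
  course and voxel-varying amplitude/sign, and making the artifact
  subspace 12-dimensional, i.e. recoverable in principle by 12
  regressors. The profiles sum to zero: a head statically displaced in
  steady state produces no artifact, so the response is to motion
  *change*, not absolute position. Kernel amplitudes are calibrated
  against the average energy of four fixed-internal-seed reference traces
  of the same configuration, so the realized artifact share of non-GM
  variance is the configured `artifact_frac` in expectation (within ~10%
  in practice) while a subject who genuinely moved more carries
  proportionally more artifact variance — preserving the cohort-level
  positive relation between mean FD and whole-brain variance.
* **Neural signal** (GM only): weighted sums of 5 low-pass-filtered
  latent series (Gaussian smoothing, σ = 2 volumes), scaled to 20% of GM
  voxel variance — a stand-in for shared resting-state networks with no
  claim of physiological realism.
* **Noise**: white Gaussian, filling the variance remainder.

The per-voxel decomposition into artifact + neural + noise is stored
exactly, which is what permits `artifact_variance_explained`: the mean,
over non-GM voxels, of the fraction of true-artifact variance inside a
regressor set's column space — a ground-truth analogue of comparing
remaining variance after regression.

What the generator does **not** emulate: physiological
(cardiac/respiratory) noise, spin-history physics, field-inhomogeneity
and susceptibility effects, spatial autocorrelation within tissue,
scanner drift beyond linear detrending, or any empirically measured
kernel family — the kernel model is a stand-in chosen for testability.
Passing tests therefore demonstrate correctness of the machinery and the
*direction* of the method's advantage under a motion model with the
structure that motivates it (prolonged, voxel-varying, low-rank
responses); they do not certify effect sizes on scanner data.

## Problem sizes

The default test-suite subjects use 135 volumes with 2,000–2,300 voxels
(300 GM / 1,500 WM / 500 CSF), which train in about half a second each;
the acceptance script and the convergence test use the full 12,000
non-GM voxels. These sizes were chosen so the entire suite exercises
every path, including ten full training runs, in well under a minute.

## Known limitations

* The CNN reaches motion lags −4…+4 around each time point; a causal
  length-9 kernel has ~2% of its damped energy at delays 5–8, which is
  irrecoverable by construction. This is inherent to two stacked size-5
  same-padded layers.
* The choice-2 loss rewards each regressor for matching *some* voxels;
  nothing forces the 12 columns to be mutually orthogonal, and the
  spanned artifact fraction plateaus near 80–90% on synthetic subjects
  rather than 100%.
* rmsFD implements a spherical-shell head model as its own convention
  (see above).
* Louvain is a heuristic; `modularity_q` reports the best of seeded
  restarts and is deterministic given the seed, but is not guaranteed to
  be the global optimum beyond the small graphs where the tests verify it
  exhaustively.
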