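# Methods

## Model

`volflow` models a distribution over volumes `x ∈ R^{w×h×d×c}` with an
invertible map `z = f(x)` onto a Gaussian latent, built from `K` levels.
Each level applies:

1. **Squeeze** — each 2×2×2 spatial block becomes 8 channels
   (`(w,h,d,c) → (w/2,h/2,d/2,8c)`); a fixed permutation with zero
   log-determinant. The element ordering is channel-minor over block
   offsets `(i,j,k)` in lexicographic order (output channel
   `((i·2+j)·2+k)·c + ch`), fixed so checkpoints are portable.
2. **L flow steps**, each composed of
   * *actnorm*: per-channel scale/bias, data-dependently initialized on the
     first training batch so every channel of that batch is standardized;
     log-det `= w·h·d · Σ_c log|s_c|`.
   * *invertible 1×1×1 convolution*: a trainable `c×c` matrix applied at
     every voxel; log-det `= w·h·d · log|det W|`, computed by direct signed
     log-determinant (channel counts here are ≤ 64, so LU parameterization
     is unnecessary). `W` is initialized as a random rotation (QR of a
     Gaussian matrix, sign fixed so `det = +1`, hence zero log-det at init).
     A fixed channel-reversal initialization is available via
     `ModelConfig.invconv="reverse"` for users who prefer a permutation
     start; the rotation is the default.
   * *affine coupling*: channels are split at `d = ⌊c/2⌋`; the first part
     passes through unchanged and parameterizes an elementwise affine map of
     the second: `y₂ = x₂ ⊙ exp(s(x₁)) + t(x₁)`, log-det `= Σ s`. `s` and
     `t` come from one shared 3-layer 3D conv net (kernels 3–1–3, ReLU,
     configurable hidden width, default 64) whose last layer is
     zero-initialized, so every coupling is the identity at initialization —
     this makes early training stable and gives exact identity/closed-form
     checks at init. `s` is bounded as `s = s_cap·tanh(raw/s_cap)`
     (default `s_cap = 2`), which prevents `exp` overflow during training
     and reduces to the raw affine form for small `s`; an unbounded
     `"identity"` parameterization is config-selectable.
3. **Split** (all levels except the last) — half the channels are factored
   out and scored under the prior; the rest continue. The prior over a
   factored half is a conditional Gaussian whose mean/log-std are produced
   from the retained half by a zero-initialized 3D convolution (exactly
   standard normal at init); `prior="standard"` selects a fixed N(0, I).
   The final level keeps all channels (no terminal split) and scores them
   under a learned (or standard) Gaussian.

The latent code is the ordered list of factored tensors plus the final
tensor; its total element count always equals `w·h·d·c`. Log-likelihood is
accumulated per sample (not per batch), so `log p(x)` is exact for each
volume: `log p(x) = Σ prior terms + Σ layer log-dets`.

Defaults: `K=3, L=4` for 32³ inputs; test-scale configurations use
`K=2, L=2` on 8³–16³ volumes. Spatial dims must be divisible by `2^K`.

## Numerical implementation

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine over NumPy arrays (`volflow.autodiff`)
implementing exactly the operators the flow needs — elementwise arithmetic,
`tanh`/`exp`/`log`, reductions, shape ops, a channel-last linear map, 3D
same-padding convolution, and `log|det|` with its `inv(W)ᵀ` gradient — each
with an analytic vector–Jacobian product, verified against central finite
differences in the test suite. Model parameters are float32 by default;
float64 is available (used by the Jacobian-oracle tests). Inversion is a
pure-NumPy path (no tape).

Training uses Adam (β = 0.9/0.999), linear learning-rate warmup (default
100 steps), and global-norm gradient clipping (default 50) to contain early
coupling-scale spikes. There is no early stopping; `max_steps` governs, and
a fixed seed reproduces the entire run (shuffling included). A non-finite
loss or activation aborts with a `TrainingDivergedError` carrying the
partial loss trajectory.

### Preprocessing

CT intensities are quantized integers (Hounsfield units). Raw volumes are
clamped to an intensity window (default −1024…1023 HU, covering air to
bone), affinely mapped to `[−1, 1]`, and uniformly dequantized (noise of one
quantization step, default 1 HU, mapped through the same affine scale).
The constant log-Jacobian `n·log(2/(high−low))` of the affine map is
returned so likelihoods can be reported as bits per dimension of the raw
HU data: `bpd = −(log p + correction)/(n·ln 2)`.

## Augmentation

*Flow strategy*: both parents are encoded, a single `α` is drawn as
`U(0,1)` mapped affinely into `[0.4, 0.6]` (equivalent in distribution to a
direct uniform draw on the band), the interpolation
`z̃ = (1−α)·z_a + α·z_b` is applied part-wise with the same `α` for every
latent part, and `z̃` is decoded. The restricted band keeps synthetic
volumes from nearly duplicating either parent; the `(1−α)`/`α` form makes
the endpoints exact in floating point. Pair selection for dataset-level
augmentation is uniform over ordered pairs of distinct inputs; parent
latents are encoded once and cached. Interpolation happens in model space
(post-preprocessing); exports are mapped back to raw units.

*Classical strategies*: baseline = independent axis flips (probability 0.5
per axis) and/or a central zoom with factor in `[1, 3]`, trilinear-resampled
back onto the original grid; nonlinear = baseline plus integer-voxel 3D
shifts (edge padding, default up to 4 voxels), 3D rotation — right-angle
rotations by default because they are exact (no resampling), free-angle
trilinear rotation optional — and additive Gaussian intensity noise
(default σ = 10 in the input's intensity units). Every strategy is
reproducible from (spec, seed, inputs, model), and every synthetic volume
carries a provenance record.

## Phantom generator

The phantom emulates the geometry the flow is meant to learn from CT
colonography VOIs, at 32³ voxels ≈ 1 mm spacing by default:

* a **wall**: a section of a randomly oriented sphere with curvature drawn
  from `[1/64, 1/20] voxel⁻¹`, passing through a jittered point near the
  volume center, randomly convex or concave, separating air lumen
  (−1000 HU) from soft tissue (per-volume HU ~ N(30, 15²));
* **polyp VOIs** add a sessile ball bump (radius 2.5–6.0 voxels, i.e.
  roughly the ≥ 6 mm lesion range at 1 mm spacing) centered on the wall
  surface, protruding into the lumen; the ground-truth mask marks the
  pre-blur protruding voxels;
* **normal VOIs** optionally (p = 0.7) carry a haustral-fold ridge: a
  half-tube of radius 1.0–2.2 voxels that follows the wall's great circle,
  so it hugs the curved surface rather than leaving it;
* rendering: Gaussian partial-volume blur (σ = 0.8 voxel), additive
  Gaussian noise (σ = 15 HU), rounding to integer HU (so dequantization in
  training is exercised), clamping to [−1024, 1023].

What it does *not* emulate: real anatomy (folds meeting at angles,
pedunculated polyps, stool/fluid, fecal tagging), scanner-specific noise
spectra and anisotropic spacing. Tests passing on phantoms therefore show
that the machinery (likelihood, inversion, interpolation, training
dynamics) is correct and that the generator carries class signal — not that
the model reaches clinical fidelity.

The polyp/normal separability probe uses three per-volume statistics:
maximum tissue protrusion past a robustly fitted wall surface (iteratively
trimmed least squares, sphere and plane candidates, better fit kept),
log-count of protruding voxels, and the elongation of the protruding voxel
cloud (ridges are elongated, sessile bumps compact). A logistic model on
these three statistics separates the default-spec classes with AUC ≈ 1.0.

## Verification strategy and problem sizes

* Every layer's and the whole model's log-determinant is checked against a
  brute-force numerical Jacobian (central differences, `slogdet`) on
  volumes of ≤ 32 elements, in float64, at tolerance 1e-3.
* Round-trip (decode∘encode) error is required < 1e-4 per layer and < 1e-3
  for composed models in float32 across a `K ∈ {1,2} × L ∈ {1,2,4}` grid on
  8³–16³ volumes.
* At identity initialization the mean prior log-density per dim on the init
  batch must equal the standard-normal density of a standardized variable,
  `−(ln 2π + 1)/2`, within 1e-3. The comparison uses a 4096-volume init
  batch: the residual is finite-sample covariance fluctuation at the Split
  layers (a rotation redistributes per-channel variance between the
  retained and factored halves) and shrinks as `1/√batch`; at small batches
  it would dominate the measurement.
* Density recovery: a `K=2, L=2` flow with coupling width 8 is trained for
  2000 steps (batch 32, lr 1e-3) on 2000 samples of a factorized Gaussian
  over 8³ volumes whose mean/std follow a period-2 spatial pattern, so its
  differential entropy is closed-form. Held-out NLL (400 fresh samples)
  must land within 0.1 nat/dim above the entropy and must not fall
  significantly (2 SE) below it — population cross-entropy cannot be below
  entropy, so a significant violation would indicate a broken likelihood.
  Width 8 is the appropriate scale here: wider couplings overfit the
  2000-sample set and inflate the held-out gap without any implementation
  error.
* The end-to-end pipeline test drives the CLI: phantom generation → 500
  training steps on 16³ VOIs → 20 flow-augmented volumes → evaluation,
  asserting a non-increasing block-averaged loss and a complete, in-band
  provenance manifest.

## Known limitations

* CPU-only and sized for small volumes (≤ 32³); no mixed precision or
  distributed training.
* Uniform dequantization only; variational dequantization is out of scope.
* The invertible convolution uses a dense log-determinant per step — fine
  for ≤ 64 channels, quadratic beyond.
* No class-conditional generation; augmentation quality for a downstream
  classifier is not evaluated here (that requires a clinical-scale study).
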