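# Methods

## Problem

Cone-beam CT (CBCT) acquired during image-guided radiotherapy suffers from
streak artifacts, spatially varying HU bias and noise relative to the
planning CT (pCT).  Paired CBCT/pCT training data are rarely available, so
the correction model must learn from *unpaired* sets of CBCT and pCT
slices.  This package implements an unsupervised corrector that couples a
cycle-consistent translation pair with a conditional adversarial diffusion
generator sampled in large strides.

## Model

**Match module.**  A generator G<sub>β</sub> translates a pCT slice
x<sup>ct</sup><sub>0</sub> into a fake CBCT slice ŷ<sup>cbct</sup><sub>0</sub>;
a second generator G<sub>β'</sub> translates it back.  PatchGAN
discriminators D<sub>β</sub>, D<sub>β'</sub> score the two translations with
the non-saturating adversarial loss (generator term −log D(fake);
discriminator term −log D(real) − log(1 − D(fake))), and an ℓ1 cycle loss
λ₁·E|x<sup>ct</sup><sub>0</sub> − ŷ<sup>ct</sup><sub>0</sub>| ties the round
trip down.  The fake CBCT gives the diffusion stage a *paired* condition for
every pCT slice without requiring registered data.

**Diffusive module.**  The forward process corrupts x₀ by
x_t = √(1−θ_t)·x_{t−1} + √θ_t·ε with an increasing variance schedule θ_t,
giving the closed-form marginal x_t = √γ̄_t·x₀ + √(1−γ̄_t)·ε with
γ_t = 1−θ_t, γ̄_t = Π γ_s.  A conditional UNet generator
G<sub>α</sub>(x_t, condition, t) predicts the *clean image* directly.
Sampling runs in strides of k: from t the sampler forms the clean estimate
ŷ₀ and draws x_{t−k} from the exact Gaussian posterior
q(x_{t−k} | x_t, ŷ₀) with effective one-step retention γ̄_t/γ̄_{t−k}; the
terminal step (t−k = 0) is noiseless.  A full correction costs exactly T/k
generator calls (4 with the defaults T = 1000, k = 250).  A conditional
discriminator D<sub>α</sub> scores transition candidates given
(x_t, condition, t), with an R1 gradient penalty
η·E‖∇ D<sub>α</sub>(x_{t−k})‖² evaluated at real samples of x_{t−k}; the
diffusive cycle loss λ₂·E|x₀ − ŷ₀| anchors the clean estimate.

**Total objective.**  L = λ₃·L_match + λ₄·L_diff + L_cyc, with
λ₃ = λ₄ = 0.5 by default.  λ₁ = λ₂ = 10 and η = 1 follow the conventions of
the cycle-consistency literature (they are not fixed by the model
definition) and are configurable.  In practice the single objective is
realized as alternating discriminator and generator phases per iteration,
the standard adversarial schedule.

**SCConv.**  The downsampling blocks of G<sub>α</sub> carry a Spatial and
Channel Reconstruction Convolution unit.  The SRU group-normalizes the
feature map, ranks channels by |γ| of the trainable GN scale (normalized to
weights W<sub>γ</sub> summing to 1), gates channels through
sigmoid(W<sub>γ</sub>) > 0.5 into an informative and a redundant stream,
and cross-reconstructs: each stream is split into channel halves and the
opposite halves are summed before re-concatenation, so every output channel
mixes both streams.  Note that sigmoid of a nonnegative weight is ≥ 0.5, so
with the strict ">" only exactly-zero importances gate off; the threshold
is exposed in `SRUParams` for that reason.  The CRU splits channels with
ratio v = 0.5, squeezes each part with 1×1 convolutions (ratio 2), extracts
rich features from the upper part with a 3×3 groupwise (g = 2) plus 1×1
pointwise convolution, supplements the lower part with a pointwise
convolution concatenated with its squeezed input, and fuses the two paths
with pooled softmax attention (SKNet style).  |γ| rather than γ is used for
the importances because the trainable scale may go negative while an
importance must be nonnegative.

## Design choices in open territory

- **θ schedule values** are not fixed by the model statement; the default
  is the standard linear ramp 1e-4 → 0.02 over T = 1000, which satisfies
  the "increasing sequence" requirement and drives γ̄_T ≈ 0.006.
- **Network internals** beyond SCConv placement are unspecified upstream;
  we use a residual UNet for G<sub>α</sub> (time embedding → MLP →
  per-block affine modulation; condition concatenated on channels), a
  residual encoder–decoder for the matchers, and PatchGAN discriminators.
  All sizes sit behind `GeneratorSpec` / `DiscriminatorSpec`.
- **Identity initialization.**  Both generator families end in a
  zero-initialized convolution whose output is added to atanh(clip(base))
  before the final tanh, where base is the generator input (matchers) or
  the condition (diffusive generator).  A freshly built model is therefore
  the identity / condition pass-through, which makes desk-scale training
  start from a sensible operating point instead of noise while keeping the
  output in [−1, 1].
- **Gradient routing.**  The condition image handed to the diffusive module
  is detached from the match-module graph; each module is trained by its
  own loss terms within the joint alternating loop.
- **Timestep sampling** uses a single scalar t per iteration drawn from
  {k, 2k, …, T}; t = 0 is excluded because no denoising step exists there.
- **Two learning-rate presets** ship ("paper" 2e-5; "paper-discussion"
  5e-4 with dropout 0.2) because both values are quoted upstream for the
  same model; the package's own desk-scale preset uses 2e-4, chosen
  between the two for tiny networks.  Optional global gradient-norm
  clipping (max-norm 1, default on) guards the known failure mode of
  runaway gradients at high timesteps under large learning rates.
- **Inference conditioning**: training conditions on the match module's
  fake CBCT; at inference the real CBCT slice takes its place.  One sample
  is emitted per seed (no ensembling).

## Numerical engine

No GPU tensor framework is assumed: the package carries a small
reverse-mode autodiff engine on numpy (`scdiff.autodiff`).  Every
vector-Jacobian product is itself built from differentiable primitives, so
gradients created with `create_graph=True` support the second derivative
the R1 penalty needs.  Convolution is unfold (im2col) + matmul with the
overlap-add adjoint; correctness is pinned by central-difference gradient
checks, including through the grad-of-grad path.  Parameters default to
float32; float64 flows through unchanged where tests need precision.

## Synthetic data

`scdiff.phantom` fabricates axial thorax phantoms from additive ellipses
(body ≈ +40 HU, lungs ≈ −800 HU, spine ≈ +700 HU, sternum and nodules),
supersampled 4× so edge pixels take partial-volume values.  Per-subject
anatomy is jittered (center sd 0.02 FOV, axes sd 5 %, HU sd 15).  CBCT-like
degradation layers sparse-view FBP streaks (45 of 360 views), a bounded
low-order polynomial shading field (40 HU), a global HU offset (25 HU) and
Gaussian noise (20 HU) — amplitudes chosen so the uncorrected CBCT sits
roughly 45 HU MAE from its pCT, the magnitude reported for real lung
CBCT/pCT pairs.  Projection and reconstruction use the parallel-beam Radon
transform and ramp-filtered backprojection of scikit-image (cubic
interpolation; rasterization grid centered on pixel N//2 to match the
transform's rotation center).  The simulator is deliberately *not* a
physics simulation: no cone-beam geometry, scatter, beam hardening or
motion.  Passing tests therefore demonstrate that the method removes the
modeled artifact classes on anatomy-like images, not clinical performance.

## Metrics

MAE, RMSE (HU), PSNR (dB) and SSIM are computed in HU after
denormalization.  PSNR's MAX and SSIM's dynamic range default to the
evaluation window width (2000 HU for [−1000, 1000]).  SSIM's default
`global` mode evaluates the index once from whole-image moments with
c1 = (0.01 L)², c2 = (0.03 L)²; a `windowed` mode (11×11 Gaussian, via
scikit-image) is available for comparability with common practice.  All
four metrics are verified against independent brute-force loop
implementations to 1e-9.

## Desk-scale experiment sizes

The end-to-end experiment trains on 100 + 100 unpaired 64×64 slices from
disjoint synthetic subjects (5 subjects × 50 slices; one subject held out),
uses the "desk" preset (base width 16, depth 2, batch 2, T = 1000,
k = 250), runs 350 iterations, and evaluates on 20 held-out paired test
slices.  These sizes keep a full run in single-digit minutes on one CPU
core while leaving enough signal for the corrected slices to beat the
uncorrected CBCT on PSNR and SSIM for most seeds; the improvement
direction, not its clinical magnitude, is the reproducible claim at this
scale.

## Degenerate inputs and tie-breaks

- `posterior_step` outside the k-stride grid raises a contract error; the
  terminal stride ignores its noise argument.
- PSNR of identical images returns +inf as a flagged sentinel.
- All-zero GN scales make the channel importances undefined and raise a
  dedicated error.
- Non-finite losses raise a `DivergenceError` carrying the last good
  checkpoint path.

## Known limitations

- The simulator's artifact classes are a caricature of clinical CBCT;
  shading is additive polynomial, noise is white Gaussian.
- Global SSIM on full slices saturates near 1 when anatomy dominates;
  window-averaged SSIM is sharper for local structure comparisons.
- Training at paper scale (512×512, tens of thousands of slices) is out of
  reach of the numpy engine; the architecture is the same, the widths and
  iteration counts are not.
- 3-D volumes are processed slice-wise; no through-plane consistency is
  enforced.
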