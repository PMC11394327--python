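# Methods

## Problem setting

Dermoscopic images of skin lesions are frequently occluded by hair, which
degrades both human reading and downstream lesion classifiers. The package
treats dehairing as conditional image-to-image generation: learn a mapping
F(x) ≈ y₀ from a hairy image x to its hair-free counterpart y₀ from a paired
dataset D = {(xᵢ, y₀ᵢ)}. Because genuinely paired hairy/hair-free photographs
of the same lesion are impractical, the pairs are manufactured by degrading
clean images synthetically.

## Diffusion formulation and conventions

The forward process is a variance-preserving Gaussian Markov chain

    q(y_t | y_{t−1}) = N(√α_t · y_{t−1}, (1 − α_t) I),

with closed-form marginal y_t = √(1 − γ_t)·y₀ + √(γ_t)·ε. The signal and
noise variances sum to one for every γ ∈ [0, 1]; this is the only radical
placement under which the two formulas are mutually consistent and define a
proper diffusion, and it is adopted throughout.

**α↔γ anchoring.** γ_t is the cumulative noise *variance* and the retention
factors satisfy 1 − γ_t = ∏_{s≤t} α_s with the product anchored at the clean
image: α₁ = 1 − γ₁ and α_t = (1 − γ_t)/(1 − γ_{t−1}) for t ≥ 2. The schedule
floor γ₀ participates only in the training noise-level density (below); it
is not a state of the chain. This keeps the consistency identity exact to
machine precision, which the tests assert at 10⁻¹².

**Schedule.** γ is linearly spaced on [γ_min, γ_max] over T + 1 knots;
defaults γ_min = 10⁻⁴, γ_max = 0.98, T = 2000 (desk-scale runs use T = 50).
Only the piecewise structure of the density is prescribed by the method; the
linear knot placement is this package's choice and is configurable.

**Training density.** During training, the noise level is drawn from
p(γ) = (1/T) Σ_t U(γ_{t−1}, γ_t): a step index t uniform on {1..T}, then γ
uniform on the half-open interval (γ_{t−1}, γ_t]. The test suite checks the
empirical CDF against the closed-form piecewise CDF (KS distance < 0.01 at
n = 10⁵).

**Loss.** The objective ‖f_θ(x, y_t, γ_t) − ε‖² is reduced by the *mean*
over elements and batch, making the loss scale-free across image sizes.

**Reverse step.** The posterior parameterization is
μ = (y_t − (1 − α_t)/√(γ_t) · ε̂)/√(α_t) with fixed variance σ²_t = 1 − α_t
(the simplest member of the stated Gaussian family; variances are not
learned).

**Pixel ranges.** External images live in [0, 1]; the diffusion operates on
[−1, 1] via an affine map at entry/exit. Intermediates that legitimately
leave the range (merged overlay images, unclipped overlay output, diffusion
iterates) are carried with an "unbounded" range marker and never silently
clipped; rendering clips explicitly.

## Denoiser

f_θ(x, y_t, γ_t) is a small U-Net operating on the channel-wise
concatenation of y_t and the conditioning image x (resized bilinearly to
match y_t when needed, so the conditioning branch is present at every
step). Stages have widths `base_channels × multiplier`, each stage a stack
of ResNet blocks (3×3 convolutions, ReLU activations, additive skip);
downsampling is 2× average pooling, upsampling nearest-neighbour with skip
concatenation. The noise level enters as a sinusoidal embedding of γ passed
through a 2-layer MLP and injected into every block as a per-channel shift —
the method prescribes *that* the network is conditioned on the step, not
how; this is the minimal standard mechanism. Inputs whose sides are not
divisible by 2^(stages−1) are reflect-padded and the output cropped.

The implementation is numpy with a hand-written reverse-mode autodiff
(`dermahair.nn`: conv2d via im2col, ReLU, pooling/upsampling, dense layers,
concatenation, MSE). No deep-learning framework is required; correctness of
the gradient path is established by central finite-difference checks at
10⁻⁴ relative tolerance, and the optimizer is Adam (default rate 10⁻⁴, the
full-scale setting). Everything is float64 — at desk scale the clarity and
testability outweigh speed.

**Determinism.** Initialization, batch order, noise-level and noise draws
all derive from the training seed. Checkpoints store parameters, Adam
moments, configs, schedule and the RNG bit-generator state, so a resumed run
reproduces the uninterrupted run bit for bit (asserted in the tests).

## Synthetic degradation generators

**Mask overlay.** With a binary mask m (1 = hair) the printed pipeline is
complement (−1·(m−1)), add, subtract 1; algebraically the unclipped result
is exactly img − m. The package computes the closed form directly — which
keeps background pixels bit-identical — and asserts the staged arithmetic
agrees to float rounding; the unclipped result (with its negative hair
values) is exposed alongside the [0, 1]-clipped rendering, because the
arithmetic as printed genuinely produces negatives. The mask is applied
identically to every channel of an RGB image. Grayscale masks from disk are
binarized at 0.5.

**Line synthesis.** N_lines segments (default 1000) are drawn per image:
x_start ~ U{0..W}, y_start ~ U{0..H} (inclusive, as specified), length
~ U{10..30}, direction d ∈ {−1, +1}, endpoints x_end = x_start + d·length,
y_end = y_start + length — i.e. 45° diagonals only. Draw order is fixed
(x, y, length, d) from one seeded generator for bit-reproducibility.
Segments are rasterized with Bresenham's algorithm, clipped at the canvas;
color defaults to black (0.0) and width to 1 px, both configurable — the
procedure prescribes geometry only, and published example imagery shows
dark strands.

## Procedural fixtures (what they do and do not establish)

`make_lesion_texture` produces a skin-toned background with low-frequency
Gaussian-filtered noise plus one darker ellipse with a smoothed boundary;
`make_procedural_hair_mask` draws thin curved polyline strands, retrying
placement so strands stay disjoint (making connected-component counts a
usable oracle). These emulate the *statistical shape* of dermoscopy data —
smooth background, a lesion-like blob, thin dark occluders — not its optics,
color calibration, stain diversity, or pathology. A green desk-scale test
therefore establishes that the pipeline is wired correctly and that the
model can learn to undo its own degradation at small scale; it says nothing
about clinical-grade dehairing fidelity, which requires real data and
full-scale training (hundreds of paired images at 256×256, T = 2000,
GPU-days).

The paired-dataset convention is two roots, `Data_Skin_with_Hair` /
`Data_Skin_without_Hair`, each with seven class subdirectories (akiec, bcc,
bkl, df, mel, nv, vasc) and matching basenames; the benchmark split reserves
100 images per class (700 total) for testing, stratified and seeded.

## Sampling

Both inference modes are first-class because the printed additive update
y_{t−1} = f_θ(y_t, x, t) + y_t is not the same operation as drawing from the
Gaussian posterior implied by an ε-prediction model; the package does not
pretend they coincide. `residual` reproduces the additive update literally
(telescoping identity y₀ = y_T + Σ_t f_θ asserted in tests); `ancestral`
(default) is the standard sampler consistent with the training loss. The
ancestral sampler optionally clips the implied denoised estimate
ŷ₀ = (y_t − √γ·ε̂)/√(1 − γ) to [−1, 1] before forming μ (`clip_denoised`,
default on) — a numerical guard that matters for lightly trained models;
`posterior_step_params` itself remains the pure parameterization. At t = 1
the mean is returned without noise. The step count T_infer is user-settable
(both very small, e.g. 10, and full T are legitimate operating points);
when T_infer < T the sampler subsamples the γ knots.

## Metrics

* **PSNR** = 10·log₁₀(MAX²/MSE); MAX defaults to 1.0 for [0, 1] images
  (255 for 8-bit); identical images return +∞ as a sentinel.
* **SSIM** is computed per sliding window (default 8×8, uniform weighting,
  population 1/N statistics) and averaged over valid windows and channels;
  C₁ = (0.01·MAX)², C₂ = (0.03·MAX)² — the conventional stabilizers, since
  only the per-patch formula is prescribed. Cross-checked against
  scikit-image under matching settings.
* **LPIPS** implements the weighted feature-space distance
  Σ_l ω_l/(H_l W_l) Σ_{h,w} ‖F_l(I₁) − F_l(I₂)‖² with an injectable
  extractor. The default is a fixed-seed random-convolution stack — fully
  deterministic and dependency-free, giving a reproducible perceptual-style
  distance for tests and reports, but *not* a calibrated perceptual metric;
  a pretrained backbone can be plugged in through the same interface. With
  the identity extractor the definition reduces exactly to MSE, which the
  tests exploit as an oracle.
* **Classification metrics** (accuracy, precision, recall, specificity, F1,
  cross-entropy) follow the textbook formulas from one-vs-rest confusion
  counts; multiclass scalars are macro-averaged (the reduction is not
  prescribed, so it is declared here). Zero denominators yield NaN
  sentinels rather than exceptions; cross-entropy floors probabilities at
  10⁻¹².

Report tables aggregate per-class means with an `Average` row equal to the
arithmetic mean of the class rows.

## Desk-scale experiment configuration

The end-to-end check trains on 24 procedural 16×16 grayscale pairs (6
synthetic strands each), T = 50, 500 iterations, and evaluates 8 held-out
pairs; the claim is mean PSNR(dehaired, clean) > mean PSNR(hairy, clean).
Choices made for this tiny regime: batch 16, base width 16 with multipliers
(1, 2) and one block per stage (a deeper net underfits badly in 500
iterations), and learning rate 2·10⁻³ — the full-scale default of 10⁻⁴
barely moves a freshly initialized float64 network in 500 steps. The margin
is modest (≈ +0.3 to +1.6 dB across seeds), as expected for 500 CPU
iterations.

## Known limitations

* The numpy denoiser is CPU-bound and float64; it is sized for ≤ 32×32
  desk-scale work, not 256×256 production inference.
* The default LPIPS backend is uncalibrated (see above).
* Line-synthesis hair is geometrically crude (straight 45° diagonals,
  constant color); mask-overlay hair darkens by exactly one intensity unit
  rather than modelling translucency or specularity.
* The residual sampler applies the network output with no rescaling, as
  printed; with an ε-trained network it is not a consistent inverse of the
  forward process and is provided for fidelity and comparison, not as the
  recommended mode.
* γ₀ = 0 exactly is permitted but not required; the default floor is 10⁻⁴.
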