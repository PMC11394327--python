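# dermahair

Hair strands in dermoscopic images occlude the very lesion features that
melanoma screening depends on. `dermahair` is a desk-scale toolkit for the
standard remedy studied in dermatologic image enhancement: *learn* to remove
the hair. It implements the full pipeline around a conditional denoising
diffusion model — synthetic hair degradation to manufacture paired training
data, the diffusion core and a numpy U-Net denoiser, two inference samplers,
and the image-quality / classification metric suite used to score dehairing
— all runnable on a laptop CPU with procedurally generated stand-ins for
real dermoscopy data.

## The model

Given pairs (x, y₀) of a hairy image x and its hair-free counterpart y₀, a
variance-preserving Gaussian diffusion corrupts y₀:

    y_t = √(1 − γ_t) · y₀ + √(γ_t) · ε,   ε ~ N(0, I)

where the cumulative noise variance γ_t runs over a schedule γ₀ < … < γ_T
(per-step retention factors α_t with 1 − γ_t = ∏_{s≤t} α_s). A conditional
U-Net f_θ(x, y_t, γ_t) — the hairy image concatenated channel-wise at every
step — is trained to predict ε by minimising

    L(θ) = E ‖f_θ(x, y_t, γ_t) − ε‖²,

with noise levels drawn from the piecewise-uniform density
p(γ) = (1/T) Σ_t U(γ_{t−1}, γ_t). At inference the sampler starts from pure
noise y_T ~ N(0, I) and iterates down to y₀, either by the Gaussian
ancestral posterior N(μ, σ²I) with

    μ = (y_t − (1 − α_t)/√(γ_t) · f_θ) / √(α_t),   σ²_t = 1 − α_t,

(default) or by plain additive refinement y_{t−1} = f_θ(y_t, x, t) + y_t
(`mode="residual"`).

Two generators manufacture the paired data:

* **mask overlay** — a binary hair mask (1 = hair) is complemented, added
  to the image and shifted down by one: the result is exactly `img − mask`,
  darkening hair pixels by a full intensity unit while leaving background
  pixels bit-identical;
* **self-supervised line synthesis** — 1000 short diagonal segments
  (length uniform in [10, 30] px, direction ±45°) are drawn at random
  positions, a cheap surrogate for real hair occlusion that needs no
  annotation.

The denoiser and its training loop are written in numpy with a small
reverse-mode autodiff (`dermahair.nn`), so the package has no deep-learning
framework dependency; gradients are validated against central finite
differences in the test suite.

## Worked example

```python
import numpy as np
import dermahair as dh

# the 2x2 mask-overlay arithmetic on a single channel
img  = dh.RasterImage(np.array([[0.3, 0.6], [0.5, 0.8]]))
mask = dh.HairMask(np.array([[1, 0], [0, 1]]))
result = dh.add_mask_hair(img, mask)
print(result.normalized_mask)          # [[0. 1.] [1. 0.]]
print(result.merged[:, :, 0])          # [[0.3 1.6] [1.5 0.8]]
print(result.final_unclipped[:, :, 0]) # [[-0.7  0.6] [ 0.5 -0.2]]
```

The complemented mask turns hair pixels into 0s; adding it to the image and
subtracting 1 leaves background values (0.6, 0.5) untouched and pushes hair
pixels a full unit down (0.3 → −0.7, 0.8 → −0.2); clipping to [0, 1] gives
the rendered hairy image with black strands.

A complete desk-scale run — train a tiny model on 24 procedural 16×16 pairs
(T = 50, 500 iterations) and dehair 8 held-out pairs:

```python
pairs = [dh.PairedSample(
             hairy=dh.synth_line_hair(clean := dh.make_lesion_texture(1000 + i, (16, 16)),
                                      n_lines=6, seed=2000 + i),
             clean=clean, label=dh.CLASSES[i % 7], id=f"s{i:03d}")
         for i in range(32)]
params, history = dh.train(pairs[:24],
                           dh.TrainConfig(learning_rate=2e-3, iterations=500,
                                          batch_size=16, seed=1),
                           dh.DiffusionConfig(T=50),
                           dh.DenoiserConfig(image_channels=1, base_channels=16))
schedule = dh.make_schedule(dh.DiffusionConfig(T=50))
restored, _ = dh.dehair(params, pairs[24].hairy, schedule, dh.SamplerConfig(seed=1))
print(f"{dh.psnr(pairs[24].clean, pairs[24].hairy):.2f} dB ->"
      f" {dh.psnr(pairs[24].clean, restored):.2f} dB")
```

On this configuration the training loss falls from ≈1.37 (first-100-step
mean) to ≈0.15, and held-out mean PSNR rises from 13.69 dB (hairy) to
14.13 dB (dehaired) — the model removes more corruption than it introduces,
which is the meaningful desk-scale claim (full-scale fidelity requires real
dermoscopy data and GPU training).

A `dermahair` console script wraps the same functions:
`make-fixtures`, `build-dataset`, `synth-hair`, `train`, `dehair`, `eval`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it generates procedural paired fixtures, exercises both degradation
generators, trains the tiny conditional diffusion model, dehaires the
held-out pairs and prints the per-class PSNR/SSIM/LPIPS report, then writes
the results JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
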