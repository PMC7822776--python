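# volflow

Exact-likelihood normalizing flows for small 3D medical-image volumes, with
latent-space interpolation as a data-augmentation method.

## The problem

Computer-aided detection (CADe) of colorectal polyps in CT colonography is
limited by the small size of available training sets: clinically significant
polyps are rare, and classical augmentation (flips, zooms, rotations) only
reshuffles the same few examples. A generative model with an *exact* and
*invertible* mapping between volumes and a Gaussian latent space offers a
stronger alternative: encode two real polyp volumes-of-interest (VOIs) to
latent codes `z_a`, `z_b`, interpolate between them, and decode — the result
is a new, realistic volume that is genuinely different from both parents.

`volflow` implements this for volumetric data:

* a 3D Glow-style flow — `K` levels of Squeeze → `L` × (actnorm →
  invertible 1×1×1 convolution → affine coupling) → Split — over
  channel-last volumes `(w, h, d, c)`, with exact log-likelihood

  `log p(x) = log p_Z(f(x)) + Σ_i log |det ∂f_i/∂x|`,

  trained by minimizing the mean negative log-likelihood
  `L(D) = −(1/|D|) Σ_{x∈D} log p(x)` with Adam (the model, its analytic
  gradients, and the optimizer are implemented on NumPy with a small
  reverse-mode autodiff engine included in the package);
* latent interpolation augmentation `z̃ = z_a + α(z_b − z_a)` with
  `α ∈ [0.4, 0.6]`, plus the classical baseline (flip, 1–3× zoom) and
  nonlinear (3D shift, rotation, Gaussian noise) comparator operators;
* a synthetic polyp-phantom generator (curved colon wall against air lumen,
  sessile polyp bumps or haustral-fold ridges, partial-volume blur,
  acquisition noise, HU-like integer intensities) so everything is testable
  without clinical data;
* NIfTI/NPZ volume I/O and a `volflow` command line with
  `phantom / train / sample / encode / augment / eval` subcommands.

## Worked example

Train a small flow on phantom polyp VOIs and generate a synthetic volume:

```python
import numpy as np
from volflow import (PhantomSpec, make_dataset, ModelConfig, TrainConfig,
                     PreprocessSpec, preprocess, train, bits_per_dim,
                     AugmentationSpec, generate_synthetic)

vois = make_dataset(60, 0, PhantomSpec(shape=(16, 16, 16), seed=0))
data, correction = preprocess(
    np.stack([v.volume for v in vois])[..., None], PreprocessSpec(),
    np.random.default_rng(0))

cfg = ModelConfig(input_shape=(16, 16, 16, 1), levels=2,
                  steps_per_level=2, hidden_width=16, seed=0)
report = train(data, cfg, TrainConfig(batch_size=12, max_steps=400,
                                      warmup_steps=50, seed=0))
model = report.final_model

res = model.encode(data[0])
print(f"bits/dim (HU units) {bits_per_dim(res, correction):.3f}")

out = generate_synthetic(data[0], data[1], model, AugmentationSpec(),
                         np.random.default_rng(7))
print(f"alpha={out.provenance['alpha']:.3f}")
```

Output:

```
bits/dim (HU units) 6.808
alpha=0.525
```

The training NLL falls from 136.8 nats/volume at step 0 to −8827.7 at step
399 (negative because the model space is continuous on `[−1, 1]`); the
bits/dim figure re-expresses the same likelihood per voxel in the original
1-HU quantization, so lower means a sharper density over raw CT values.
The synthetic VOI sits mid-way between its parents in latent space
(`alpha` is always drawn inside `[0.4, 0.6]`) and differs from both in
voxel space.

The same pipeline from a shell:

```sh
volflow phantom --n-polyp 100 --n-normal 100 --shape 32 --seed 1 --out vois/
volflow train --config config.yaml --data vois/ --out model.npz
volflow augment --ckpt model.npz --data vois/ --n 100 --strategy flow --seed 7 --out synth/
volflow eval --ckpt model.npz --data vois/ --labels vois/labels.tsv --out report.json
```

Every command writes a `manifest.json` (config, seed, input hashes) beside
its outputs; `augment` also writes a `provenance.tsv` recording, for each
synthetic VOI, its two parents and the drawn `alpha`.

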