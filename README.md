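# idman — super-resolution for medical CT images

Single-image super-resolution (SISR) for grayscale CT slices.  CT
acquisitions are often resolution-limited by hardware and dose; SISR
reconstructs a high-resolution (HR) image from one low-resolution (LR)
input so that edges, fine texture and small structures survive better
than with plain interpolation.  The package is aimed at researchers who
want a fully inspectable, CPU-reproducible SR pipeline: every stage —
synthetic data, degradation, network, training, metrics — is pure
Python/NumPy and verifiable at desk scale.

## The model

IDMAN (information distillation and multi-scale attention network) is a
deep residual CNN operating at LR resolution with sub-pixel upsampling:

    I_SR = H_rec(H_up(H_dfes(H_sfe(I_LR))))

The trunk (DFES) stacks G groups × B blocks with skip connections at
block, group and trunk level.  Each block refines features by
**information distillation**: three channel-splitting steps each retain
d channels (1×1 conv) and pass the coarse remainder on (3×3 conv +
identity + ReLU); the four retained slices are concatenated and fused
(1×1 conv).  A **multi-scale attention block** then rescales channels
with a sigmoid gate computed from the globally pooled descriptor through
parallel k = 3 and k = 5 branches, each wrapping a squeeze/excite
bottleneck (reduction ratio r).  Trunk convolutions use **weight
normalization** (w = g·v/‖v‖).  Training minimizes L1 loss with Adam,
lr(t) = lr₀·0.5^⌊t/T⌋, on randomly augmented LR/HR patch pairs produced
by antialiased bicubic degradation.  Reconstructions are scored by PSNR
(10·log₁₀(MaxValue²/MSE) dB) and SSIM (Gaussian 11×11 window) against
the bicubic baseline.  Details and all defaults: `docs/methods.md`.

Because clinical CT archives are not required for verification, the
package includes a seeded phantom generator producing CT-like images
(smooth backgrounds, elliptical organs of distinct attenuation, a
sharp bone-like ring, mild noise).

## Worked example

```python
import numpy as np
from idman import (IDMANSuperResolver, BicubicUpscaler,
                   PhantomSpec, generate_phantom)

rng = np.random.default_rng(7)
hr = [generate_phantom(PhantomSpec(size=64, n_ellipses=3,
                                   seed=int(rng.integers(2**31))))
      for _ in range(40)]
train_hr, test_hr = hr[:32], hr[32:]

sr = IDMANSuperResolver(scale=2, n_groups=2, n_blocks=2, width=16,
                        distill_channels=4, reduction_ratio=4,
                        max_iters=600, lr0=2e-3, lr_patch=16, seed=0)
sr.fit(train_hr)   # LR inputs are derived internally by bicubic degradation
print(f"IDMAN   held-out PSNR: {sr.score(test_hr):.2f} dB")
print(f"bicubic held-out PSNR: {BicubicUpscaler(scale=2).fit().score(test_hr):.2f} dB")
```

Output (about a minute on one CPU core):

```
IDMAN   held-out PSNR: 20.42 dB
bicubic held-out PSNR: 19.33 dB
```

Even this tiny network (2 groups × 2 blocks, 16 channels, 600
iterations) recovers ~1.1 dB over bicubic interpolation on held-out
phantoms; the sharp bone edges that alias under downsampling are where
the learned model wins.  `score` returns mean PSNR in dB over the test
images after ×2 degradation and reconstruction — higher is better, and
+1 dB corresponds to ~21% lower MSE.

The same workflow is available from the shell:

```bash
idman make-data --out data --seed 7
idman train --data data --out run --seed 7
idman eval  --data data --checkpoint run/model.npz --out eval
idman sr    --input data/test_0000.png --checkpoint run/model.npz --out sr.png
idman ablate --data data --out ablation --seed 7   # 2x2 module grid
```

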