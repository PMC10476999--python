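# ctdenoise

Deep-learning denoisers for low-dose CT (LDCT) are usually trained with a
per-pixel loss (MAE/MSE). That objective treats every region of the slice the
same, although quantum noise is much harder to remove near high-attenuation
structures and in texture-rich tissue, and it rewards over-smoothing, wiping
out exactly the high-frequency texture a radiologist reads. `ctdenoise`
implements a hybrid training loss that addresses both failure modes, together
with everything needed to exercise it end to end without clinical data: a
projection-domain LDCT simulator, a synthetic abdomen phantom generator,
PSNR/SSIM metrics, and a small reference training harness written in plain
NumPy (analytic gradients, no deep-learning framework required).

## The loss

For a denoiser output x and normal-dose target y,

```
L_hybrid(x, y) = α₁ · L_WP(x, y) + α₂ · L_HF(x, y)
```

**Weighted patch loss (WPLoss).** Both images are tiled into N non-overlapping
patches. With lᵢ the MAE of patch i,

```
wᵢ = clamp( lᵢ / median(l),  0.25, 4 ),      L_WP = Σᵢ wᵢ · lᵢ
```

Patches that are currently hard to denoise (large lᵢ relative to the median
patch) get proportionally more gradient; well-fitted patches are damped so
they are not over-updated. The weights are constants for backpropagation — no
derivative flows through the median — and the clamp prevents an outlier patch
from destabilizing training.

**High-frequency loss (HFLoss).** With F the 2-D DFT and G a high-pass filter
(ideal circular, cutoff radius r₀ = 0.1 of the centered frequency grid, DC
always removed),

```
HP(x) = Re( F⁻¹( G ⊙ F(x) ) ),      L_HF = mean | HP(x) − HP(y) |
```

so the loss directly penalizes missing edge/texture content, and differences
that are a constant offset cost nothing.

## Worked example

```python
import numpy as np
from ctdenoise import (PhantomSpec, DoseModel, Geometry, generate_phantom,
                       simulate_ldct, NormalizationStats, normalize,
                       HybridConfig, WeightConfig, hybrid_loss, psnr, ssim)

ndct = generate_phantom(PhantomSpec(size=64, seed=7))
ldct = simulate_ldct(ndct, DoseModel(N0=1e5, dose_fraction=0.25, seed=7),
                     Geometry(n_angles=90))
print(f"LDCT vs NDCT: PSNR {psnr(ldct, ndct):.2f} dB, SSIM {ssim(ldct, ndct):.4f}")

stats = NormalizationStats.from_images([ndct])
report = hybrid_loss(normalize(ldct, stats).pixels, normalize(ndct, stats).pixels,
                     HybridConfig(weight_config=WeightConfig(4, 4)))
print(f"WPLoss {report.wp_loss:.4f}  HFLoss {report.hf_loss:.4f}  "
      f"hybrid {report.hybrid_loss:.4f}")
print("patch weights:", np.round(report.patch_grid.weights, 2))
```

prints

```
LDCT vs NDCT: PSNR 26.64 dB, SSIM 0.6330
WPLoss 1.6253  HFLoss 0.1044  hybrid 1.7297
patch weights: [0.69 0.9  0.94 0.7  1.03 0.88 0.98 1.03 1.02 1.12 1.12 1.09 0.71 1.09
 1.05 0.73]
```

The quarter-dose simulation costs about 6 dB of PSNR against the clean
phantom. The 4×4 patch weights show the adaptivity: corner patches that are
mostly air (little residual noise after reconstruction) are down-weighted to
~0.7, while the noisier interior patches climb above 1, so a denoiser trained
with this loss spends its capacity where the noise actually is.

A quarter-dose LDCT image is simulated physically: the HU phantom is
converted to linear attenuation, forward projected (parallel-beam Radon
transform), photon counts are drawn per ray as `K·Poisson(N0_eff·exp(−pᵢ))`
with `N0_eff = N0 · dose_fraction`, log-converted back to line integrals, and
reconstructed with filtered back-projection. Quarter dose therefore doubles
the reconstruction noise (1/√dose scaling). A fast image-domain Poisson mode
is available when projection simulation is not needed.

## Command line

```
ctdenoise generate --n 60 --size 224 --dose-fraction 0.25 --seed 7 --out data/
ctdenoise train    --config run.yaml --data data/ --out runs/hybrid
ctdenoise denoise  --model runs/hybrid/model.npz --stats runs/hybrid/stats.json \
                   --input data/ --out denoised/
ctdenoise evaluate --pred denoised/ --ref data/ --out metrics.csv
ctdenoise ablate   --config run.yaml --data data/ --out runs/ablation
```

`ablate` trains the reference denoiser once per loss variant (MAE baseline,
WPLoss, MAE+HFLoss, hybrid) with shared seeds and data and tabulates
mean ± std PSNR/SSIM on the test split.

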