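# Methods

This note records the mathematical definitions, numerical conventions,
default parameters and known limitations of `ctdenoise`. All symbols refer
to 2-D single-slice images; x is the denoiser output (or the low-dose
image when the loss is evaluated standalone) and y the normal-dose target.

## 1. Weighted patch loss

The image pair is partitioned into N non-overlapping rectangular patches
(default grid 4×4, so N = 16); image dimensions must be exactly divisible
by the grid. With lᵢ the mean absolute error of patch i,

```
wᵢ = clamp( lᵢ / median(l₁ … l_N),  w_min, w_max ),    L_WP = Σᵢ wᵢ lᵢ
```

with clamp bounds w_min = 0.25 and w_max = 4. Conventions:

- **Sum, not mean**, over patches: the unweighted special case (all wᵢ = 1)
  equals N times the image MAE, and the worked fixture with patch MAEs
  [1, 2, 3, 4] yields weights [0.4, 0.8, 1.2, 1.6] and L_WP = 12.
- **Even N median** is the mean of the two central order statistics.
- **Zero median** (e.g. identical images): all weights are set to 1, so the
  loss degrades gracefully to N·MAE.
- **Detached weights.** For gradients the weights are treated as constants;
  no derivative flows through the median or the clamp. The analytic
  gradient is therefore ∂L_WP/∂xₚ = wᵢ · sign(xₚ − yₚ)/|patch| for pixel p
  in patch i, and the test suite verifies it against finite differences of
  the frozen-weight loss. This keeps the objective piecewise smooth and
  avoids the discontinuous gradient the median ranking would introduce.

## 2. High-frequency loss

DFT convention is the unnormalized forward transform with the 1/(mn)
factor on the inverse (the `numpy.fft` convention), so
F([[1,2],[3,4]]) = [[10,−2],[−4,0]]. The high-pass operator is

```
HP(x) = Re( F⁻¹( G ⊙ F(x) ) ),      L_HF = (1/mn) Σ | HP(x) − HP(y) |
```

The default filter G is the ideal circular high-pass on the normalized
centered radius ρ(u,v) = √(fᵤ² + fᵥ²) with fᵤ, fᵥ the per-axis
`fftfreq` values: G = 1 where ρ > r₀, default cutoff r₀ = 0.1. A Gaussian
alternative 1 − exp(−ρ²/2r₀²) is available. In every case the DC bin is
forced to zero, so constant offsets cost nothing, and the mask is symmetric
under frequency negation, which makes HP a real, self-adjoint operator.
Self-adjointness gives the closed-form gradient

```
∂L_HF/∂x = HP( sign(HP(x − y)) ) / (mn)
```

verified against finite differences to 1e-4 relative error.

## 3. Hybrid loss

```
L_hybrid = α₁ L_WP + α₂ L_HF,    defaults α₁ = α₂ = 1
```

Both terms are degree-1 homogeneous, so the hybrid loss scales linearly
with the image pair. Training variants exposed by the trainer:

- `mae` — plain image MAE (baseline);
- `wp` — pure L_WP;
- `hf` — MAE + α₂ L_HF. The frequency term is always anchored to a
  per-pixel base loss: by construction L_HF is blind to the low-pass band,
  so used alone it cannot constrain the reconstruction's smooth content
  and measurably degrades PSNR;
- `hybrid` — the full objective above.

## 4. Low-dose CT simulation

HU to linear attenuation: μ = μ_water (1 + HU/1000) with
μ_water = 0.0192 mm⁻¹. The projection-domain chain is

1. forward parallel-beam Radon transform of μ (scikit-image `radon`,
   `circle=False`, scaled by the pixel spacing so line integrals are
   dimensionless);
2. photon counts per ray: c = K · Poisson(N0_eff · e^(−p)) with
   N0_eff = N0 · dose_fraction, default N0 = 10⁵ incident photons per ray,
   detector gain K = 1, Philox counter-based generator keyed by the seed;
3. log inversion p̂ = ln(K·N0_eff / max(c, K)) — counts are floored at one
   photon so zero-count rays stay finite;
4. filtered back-projection (scikit-image `iradon`, ramp filter by
   default, Hann optional), then back to HU.

This reproduces the two statistics that matter for denoiser training:
counts are Poisson (dispersion index ≈ 1), and flat-region reconstruction
noise scales as 1/√dose_fraction (quarter dose ≈ 2× the noise std, the
suite checks the ratio lands in [1.7, 2.3] over 20 seeds). The noiseless
Radon→FBP round trip reconstructs a smooth phantom to < 5% relative RMSE
inside the reconstruction circle at 180 views; exact inversion is not
attainable for an interpolating discrete transform.

A cheap image-domain mode applies Poisson noise per pixel through an
effective path length L_eff = 100 mm instead of projecting; it has roughly
the right dose scaling but no streak correlations, and is intended for
fast tests only.

## 5. Phantom generator

Anthropomorphic-ish abdominal slices built from ellipse composition on a
350 mm body extent (pixel spacing = 350/size mm): elliptical body outline,
subcutaneous fat ring, soft-tissue interior, randomized organ ellipses, a
liver with an optional low-contrast lesion (default −20 HU), a spine bone
insert, plus band-limited tissue texture synthesized by Gaussian spectral
shaping (default amplitude 25 HU, correlation length 3 px). HU palette:
air −1000, fat −90, soft tissue 40, liver 55, bone 700; values clipped to
[−1000, 2000]. Sizes must be ≥ 32 and divisible by 4 (the patch grid).
The generator provides controllable, reproducible structure at CT-realistic
contrast scales; it does **not** emulate beam hardening, scatter, partial
volume, anatomical variability, or out-of-plane effects.

Datasets are split 6:2:2 into train/val/test with per-image seeds derived
via `SeedSequence([master, index])`, recorded in a JSON manifest;
regeneration from the manifest is bit-identical.

## 6. Reference trainer

A deliberately small residual CNN written in NumPy with analytic
backpropagation (im2col convolutions): 5 conv 3×3 layers, 32 channels,
ReLU, output = input − predicted residual. Kernels are initialized
N(0, 0.01²), biases zero, so the untrained network is near-identity —
appropriate for residual denoising. Optimizer is Adam with β₁ = 0.5,
β₂ = 0.9; the default learning rate is 1e-4, halved every 50 epochs.
Training operates in the normalized domain (HU − mean)/std with
dataset-level statistics computed from the training-split normal-dose
images; metrics are always reported in HU.

The desk-scale configurations used by the test suite and the acceptance
script (64×64 images, 30 pairs, 25 epochs, learning rate 1e-3) are the
package's own choices, sized so a full four-variant ablation runs in
minutes on one CPU while still separating trained from untrained behavior
by several dB of PSNR.

## 7. Metrics

PSNR = 10 log₁₀(R²/MSE) with R the data range (default: target max−min);
identical images return +inf. SSIM follows the standard Gaussian-weighted
formulation (σ = 1.5, 11×11 window, K₁ = 0.01, K₂ = 0.03, population
covariance), for which two constant images 100 vs 110 at R = 255 give
0.995476 and the uniform-difference PSNR fixture (Δ = 16, R = 255) gives
24.0484 dB. Rectangular ROI metrics are supported for lesion-local
evaluation.

## 8. Limitations

- Parallel-beam geometry only; no fan/cone beam, no bowtie filtration,
  no electronic noise floor beyond the one-count clamp.
- The NumPy trainer is a reference implementation for validating the loss
  and its gradients, not a performance-competitive denoiser; desk-scale
  results demonstrate direction (each variant improves PSNR over the
  noisy input), not state-of-the-art magnitudes.
- The ideal high-pass filter has a sharp band edge and therefore spatial
  ringing; the Gaussian mask is provided where smooth roll-off matters.
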