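# Methods

## Image formation model

The simulator implements linear structured-illumination image formation on a
square pixel grid. A fluorophore density S(r) (arbitrary units, r in pixels,
origin top-left, x = column, y = row) is excited by a sinusoidal fringe

    I_{θ,φ}(r) = I0 [1 + m cos(2π k0 (cosθ, sinθ)·r + φ)],

blurred by the system PSF H(r) and offset by an out-of-focus background:

    D_{θ,φ}(r) = [I_{θ,φ}(r) S(r)] ⊗ H(r) + B_out.

An acquisition is 3 orientations (0°, 60°, 120°) × 3 phases stepped by π/2
(φ0, φ0+π/2, φ0+π), plus a uniform-illumination widefield reference.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| wavelength λ | 470 nm | excitation wavelength |
| NA | 0.6 | numerical aperture |
| pixel size | 30 nm | grid sampling |
| PSF model | Gaussian, FWHM = 0.51 λ/NA | `airy` (jinc²) available |
| OTF cutoff kc | 2 NA/λ | converted to cycles/pixel |
| k0 | 0.66 kc | fringe frequency of the standard bead demo |
| m | 0.9 | modulation depth (high-contrast projected fringes) |
| I0 | 1.0 | mean illumination |
| noise | off | Poisson(photon-scaled) + Gaussian read noise available |

The fringe-to-cutoff ratio 0.66 reproduces the geometry of a DMD projector
with four mirror columns per fringe period; the bead demo uses 200 nm beads,
the common calibration target. Defaults without an authoritative physical
value (photon budget, pixel size) were chosen once for realism — typical
sCMOS sampling near Nyquist for this NA — and are all configurable.

Convolution is FFT-based on a reflect-padded grid (pad = kernel half-width),
cropped back, which avoids wrap-around artifacts; a `periodic` boundary mode
exists for exact photon-count conservation checks. The PSF kernel is
truncated and renormalized; an encircled-energy check (closed-form: erf² for
the Gaussian, 1 − J0² − J1² for the Airy pattern) rejects supports that hold
too little energy. The Airy threshold defaults to 0.80 because its rings
decay so slowly that 99% energy needs a support ~60× the first-zero radius.

## Spatial-domain reconstruction

With the phase step fixed at π/2, neighbouring phase frames subtract to

    d12 = √2 m I0 [cos(2π k0·r + φ0 − π/4) S] ⊗ H
    d23 = √2 m I0 [cos(2π k0·r + φ0 + π/4) S] ⊗ H,

two quadrature measurements of the fringe-modulated sample. Anything common
to the three frames — notably the out-of-focus background, constant or
spatially varying — cancels exactly; this is the optical-sectioning property
of the differential step. The analytic signal z = d12 − i·d23 equals
√2 m I0 [S e^{i(2π k0·r + φ0 − π/4)}] ⊗ H, so the modulus |z| removes both
the fringe carrier and the unknown global phase φ0 (no fringe-phase
estimation stage exists, by construction). The constant is √2 m I0, not the
2 m I0 sometimes quoted: cos x + sin x = √2 cos(x − π/4) fixes the radical;
all constant factors cancel under normalization. The per-orientation moduli
are summed (summing the complex fields instead would reintroduce carrier
fringes at the orientation difference frequencies without narrowing the
point response — see limitations).

### What this reconstruction does and does not improve

For an isolated point source S = δ the pipeline returns exactly
|z| = √2 m I0 H(r − r0): the impulse response *is* the widefield PSF, so the
Gaussian-fit FWHM of an isolated bead does not shrink (the bead calibration
experiment measures a widefield/reconstruction ratio of ≈ 1.00, slightly
below 1 because the fringe phase varies across a 200 nm bead). The lateral
gain of the method is a *two-point* property: nearby emitters acquire
different carrier phases, and their difference produces a valley in the
modulus image that widefield imaging cannot form. In the standard geometry
(k0 = 0.66 kc) the line-pair experiment resolves 250 nm separations
(valley contrast ≥ 0.1) where widefield needs ≈ 425 nm — a two-point gain of
≈ 1.7, consistent with the band-expansion bound 1 + k0/kc = 1.66. Background
rejection, by contrast, is exact (machine precision) and holds for arbitrary
background maps.

## Frequency-domain reference

A metadata-driven frequency-domain reconstructor serves as an independent
cross-check: per orientation the three spectra are unmixed with the matrix
rows [1, ½e^{−iφ_j}, ½e^{+iφ_j}], side bands are recentred by exact
sub-pixel phase ramps (the shifted OTF is evaluated by a separable
generalized DFT of the kernel, so sub-pixel k0 is exact), and all bands are
combined with a generalized Wiener filter (default w = 0.15) followed by a
triangle apodization to the extended cutoff kc + k0. The apodization is the
standard ringing suppression of frequency-domain SIM codes; without it half
the output pixels are clipped negative ringing. Nothing is estimated from
the data — fringe parameters come from acquisition metadata — so this is a
reference implementation, not a parameter-estimation pipeline. On the
standard bead stack the two routes correlate at r ≈ 0.86 (both normalized);
the Wiener route is sharper because it deconvolves, the spatial route is
~an order of magnitude cheaper and background-immune.

## Low-light enhancement

The enhancement treats an image as reflectance × illumination and divides
out a smooth illumination estimate. Inputs already in [0, 1] are used as-is;
integer images are scaled by their dtype maximum; anything else is min-max
normalized per channel.

1. **Exposure analysis.** The value channel (per-pixel channel max) is tiled
   into non-overlapping n × n blocks for n ∈ {2, 4, 6, 8} (reflect-padded to
   a multiple of n). Each block gets an exposure fitness fbc ∈ [0, 1] —
   by default its mean brightness, optionally plus λc × block std for a
   contrast-sensitive reading — and is flagged over-exposed when fbc > 0.65
   (0.5 reads as optimal exposure; the boundary 0.65 itself is well-exposed).
   Per-pixel scores fuse the four scales with weights ∝ 1/n
   (≈ 0.48/0.24/0.16/0.12) and the mask thresholds the score at 0.5.
2. **Attention map.** A = 0.1 on masked pixels, 1.0 elsewhere.
3. **Illumination init.** L0 is the channel max, but inside the mask it is
   capped at the 95th percentile of L0 over well-exposed pixels, so
   saturated values never seed the estimate.
4. **Refinement.** Projected gradient descent on
   loss(L) = Σ A (L − L0)² + λ_tv TV(L), TV anisotropic (sum of absolute
   forward differences), λ_tv = 0.15, 100 iterations, step 0.05, with the
   projection clip(L, channel_max, 1) keeping reflectance ≤ 1. The TV
   subgradient is smoothed (Charbonnier, δ = 1e-3) and the step backtracks
   (persistent halving) whenever a move would increase the loss, so the
   recorded loss trace is non-increasing; with backtracking disabled, more
   than 5 consecutive loss increases raise an error suggesting a smaller
   step.
5. **Output.** R = x / L^γ (γ = 0.8) clipped to [0, 1], composed with the
   original through the attention weights: out = w R + (1 − w) x with
   w = A/A_high. The composition is what makes the overexposure suppression
   effective: under the reflectance ≤ 1 projection the attention weight on
   the fidelity term alone cannot change the result at saturated pixels
   (the lower bound is active there regardless of A), whereas gating the
   output leaves saturated regions essentially at their input values.

On the half-dark (0.15) / half-saturated (0.98) fixture the dark half gains
+356% while the saturated half gains +0.16% (vs +1.63% with the A ≡ 1
ablation — a 10× larger dark/saturated gain ratio). Because a boosted region
crosses the 0.65 exposure threshold and is then itself attenuated, repeated
enhancement saturates instead of diverging (second-pass mean change ≈ 5% of
the first). For a uniform mid-gray image the output is the plain gamma map
x^{1−γ} (0.5 → 0.87): a mild, spatially uniform brightening.

This is a per-image, training-free optimization of the same decomposition
and constraints used by learning-based Retinex enhancers; there is no
network, no training data, and no denoising stage.

## Metrics

- **FWHM**: least-squares Gaussian fit A e^{−(x−μ)²/2σ²} + c with
  moment-based initialization; FWHM = 2√(2 ln 2) σ × pixel size. Fits with
  R² < 0.5 raise; bead aggregates use only fits with R² ≥ 0.9. Per bead,
  horizontal and vertical profiles through the peak are fitted and averaged;
  beads with overlapping windows are skipped with a warning.
- **SSIM**: 11 × 11 Gaussian window (σ = 1.5), standard stabilizers,
  unit data range (scikit-image).
- **PSNR** = 10 log10(1/MSE) on unit-range images, reported as the sentinel
  100 dB for identical inputs.
- **RMSE** on the 0–255 scale, the convention of the enhancement literature
  (PSNR = 20 log10(255/RMSE) holds to machine precision).
- **CII**: no canonical formula exists, so it is implemented as the common
  definition in the enhancement literature — the ratio of mean local RMS
  contrast in 3 × 3 windows, processed over reference (window size
  configurable). Identical images give exactly 1.

## Synthetic data: what it covers and what it does not

The generator reproduces the geometry and linear optics of a fringe-projection
acquisition: ideal sinusoidal fringes with an exact π/2 step, a
shift-invariant 2-D PSF, an additive (possibly smooth) background, and
optional Poisson + Gaussian noise. It does not model fringe-phase jitter or
drift, modulation-depth variation across the field, 3-D defocus structure,
polarization, photobleaching, or camera fixed-pattern effects. Passing tests
therefore certify the algorithmic contracts (oracle equivalence, exact
background cancellation, phase invariance, classification and metric
contracts) — not robustness to the calibration errors of a physical
instrument, which for this method would enter through the assumed-exact π/2
step.

## Problem sizes

Tests and the acceptance script use 32×32 random phantoms (17 px PSF kernel,
60 nm pixels) for oracle-equivalence checks, the 256×256 / 8-bead standard
phantom for resolution and cross-method experiments, 128×128 grids for the
line-pair sweep, and a 64×64 enhancement fixture; the full suite runs in a
few seconds on one CPU. These sizes are the package's chosen study
conditions; all experiments scale by changing the corresponding parameters.

## Known limitations

- Isolated-point FWHM is not improved (see above); claims of FWHM-measured
  gains for this class of method are not reproducible from its own forward
  model and should be read as two-point resolvability gains.
- Fringe parameters (k0, θ, φ0) are taken as known; there is no estimation
  from data on either reconstruction route.
- The enhancement's exposure classifier is brightness-based by default; the
  contrast-based reading is available via λc but the two disagree on
  uniformly bright, low-contrast regions.
- Output grids match input grids (no upsampling); nonlinear/saturated SIM
  and 3-D SIM are out of scope.
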