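# sdsim — spatial-domain SIM reconstruction with low-light enhancement

`sdsim` is a toolkit for π/2 phase-shifted structured illumination microscopy
(SIM): a forward simulator of 9-frame fringe-projection acquisitions, a
spatial-domain reconstruction that works entirely with image differences and
an analytic-signal modulus (no Fourier-domain parameter estimation), an
overexposure-aware Retinex low-light enhancer for the reconstructed images,
and resolution/quality metrics. It is aimed at microscopy-methods developers
who want a compact, fully synthetic, reproducible testbed for this family of
reconstructions.

## The method

A sample S(r) is illuminated with sinusoidal fringes
I(r) = I0[1 + m cos(2π k0·r + φ)] at three orientations, each with three
phases stepped by exactly π/2, giving frames
D_{i,j} = (I_{i,j} S) ⊗ H + B_out. Subtracting neighbouring phases cancels
the out-of-focus background B_out exactly and yields two quadrature images;
assembled as a complex field,

    z = d12 − i·d23 = √2 m I0 [S e^{i(2π k0·r + φ0 − π/4)}] ⊗ H,

whose modulus |z| demodulates the fringe carrier without knowing φ0. The
per-orientation moduli are summed into the reconstruction. The toolkit also
ships a metadata-driven frequency-domain reconstructor (band separation +
generalized Wiener filter + apodization) as an independent cross-check, and
an enhancement stage that estimates a smooth Retinex illumination L by
minimizing an attention-weighted fidelity + total-variation loss, truncating
over-exposed pixels out of the initialization (multi-scale block exposure
analysis, blocks flagged when their exposure fitness exceeds 0.65) and
gating the output so saturated regions are not boosted further.

Two properties matter when interpreting results (details in
`docs/methods.md`): background rejection is exact by construction, and the
lateral resolution gain is a *two-point* property — nearby emitters become
separable through their fringe-phase contrast — while the FWHM of an
isolated point is unchanged (the impulse response of the difference/modulus
pipeline is the widefield PSF itself).

## Worked example

```bash
python examples/line_pair_resolution.py
```

```
 separation (nm)  widefield dip  reconstruction dip
             250         -0.139               0.137
             300         -0.119               0.554
             400          0.034               0.467
             425          0.112               0.487
             500          0.351               0.581

smallest resolved separation, widefield:      425 nm
smallest resolved separation, reconstruction: 250 nm
two-point resolution gain: 1.70 (band-expansion bound for k0 = 0.66 kc is 1.66)
```

Line pairs 250 nm apart — far below the widefield limit for NA 0.6 at
470 nm — show a clear valley (contrast 0.14) after reconstruction, while the
widefield image first resolves them at 425 nm: a two-point gain of 1.70,
close to the theoretical band-expansion bound 1 + k0/kc = 1.66.

```bash
python examples/low_light_enhancement.py
```

```
 attention: dark half gain +356.2%, saturated half gain +0.16%, dark/saturated ratio 2186
  ablation: dark half gain +356.2%, saturated half gain +1.63%, dark/saturated ratio 219
```

On a half-dark/half-saturated image the enhancer brightens the dark half
3.6× while moving the saturated half by 0.16%; with the attention map
disabled the saturated half is boosted ten times more.

Other examples: `simulate_and_reconstruct.py` (bead calibration, FWHM
reports, background immunity), `quality_metrics.py` (SSIM/PSNR/RMSE/CII),
`full_pipeline.py` (one-call pipeline with manifest and provenance).

The same stages are available from the shell:

```bash
sdsim simulate --kind beads --n 8 --size 256 --seed 7 -o stack.tif
sdsim reconstruct stack.tif -o sr.tif
sdsim enhance sr.tif -o sr_llie.tif
sdsim evaluate sr_llie.tif --ref stack_widefield.tif --json report.json
sdsim demo --output-dir runs/demo
```

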