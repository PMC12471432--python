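import math

import numpy as np
import pytest

from sdsim.reconstruct import (
    ComplexField,
    combine_orientations,
    complex_signal,
    demodulate,
    fdr_reference,
    phase_differences,
    reconstruct,
)
from sdsim.simulate import make_phantom

from conftest import SMALL, small_stack


def fringe_phase(size, theta_deg, k0, phi0=0.0):
    gy, gx = np.mgrid[0:size, 0:size].astype(float)
    t = math.radians(theta_deg)
    return 2 * math.pi * k0 * (math.cos(t) * gx + math.sin(t) * gy) + phi0


def fft_demodulation_oracle(density, psf, cfg, theta_deg):
    """Independent frequency-domain evaluation of the demodulated envelope:
    sqrt(2)*m*I0*|FT^-1[s(k - k0) h(k)]| via the modulated-sample spectrum."""
    n = density.shape[0]
    psi = fringe_phase(n, theta_deg, cfg.k0_cycles_per_px, cfg.phi0_rad)
    kern = np.zeros((n, n))
    s = psf.size_px
    kern[:s, :s] = psf.kernel
    kern = np.roll(kern, (-psf.half_width, -psf.half_width), axis=(0, 1))
    field = np.fft.ifft2(np.fft.fft2(density * np.exp(1j * psi)) * np.fft.fft2(kern))
    return math.sqrt(2) * cfg.m * cfg.i0 * np.abs(field)


class TestPhaseDifferences:
    def test_identical_frames_cancel(self):
        _, _, _, stack = small_stack(seed=0, m=0.0)
        pair = phase_differences(stack, 0)
        assert np.allclose(pair.d12, 0, atol=1e-12)
        assert np.allclose(pair.d23, 0, atol=1e-12)

    def test_constant_offset_is_removed(self):
        _, _, _, stack = small_stack(seed=1)
        pair = phase_differences(stack, 1)
        stack.frames[1] += 3.7
        shifted = phase_differences(stack, 1)
        scale = np.abs(stack.frames[1]).max()
        assert np.abs(pair.d12 - shifted.d12).max() < 1e-12 * scale
        assert np.abs(pair.d23 - shifted.d23).max() < 1e-12 * scale

    def test_missing_orientation_raises(self):
        _, _, _, stack = small_stack(seed=1)
        with pytest.raises(ValueError, match="orientation 5"):
            phase_differences(stack, 5)

    def test_difference_matches_spatial_convolution_oracle(self):
        """d12 must equal sqrt(2) m I0 [cos(2 pi k0.r + phi0 - pi/4) S] (x) H
        computed by brute-force direct convolution."""
        from scipy.signal import fftconvolve

        phantom, psf, cfg, stack = small_stack(seed=2, phi0=0.3)
        pair = phase_differences(stack, 0)
        psi = fringe_phase(stack.shape[0], cfg.thetas_deg[0],
                           cfg.k0_cycles_per_px, cfg.phi0_rad)
        modulated = np.cos(psi - math.pi / 4) * phantom.density
        oracle = math.sqrt(2) * cfg.m * cfg.i0 * fftconvolve(
            modulated, psf.kernel, mode="same")
        assert np.abs(pair.d12 - oracle).max() < 1e-6 * np.abs(oracle).max()


class TestComplexSignal:
    def test_zero_pair_gives_zero_field(self):
        _, _, _, stack = small_stack(seed=0, m=0.0)
        field = complex_signal(phase_differences(stack, 0))
        assert np.allclose(field.z, 0)

    def test_real_part_is_first_difference(self):
        _, _, _, stack = small_stack(seed=3)
        pair = phase_differences(stack, 0)
        field = complex_signal(pair)
        np.testing.assert_array_equal(field.z.real, pair.d12)
        np.testing.assert_array_equal(field.z.imag, -pair.d23)

    def test_modulus_is_global_phase_invariant(self):
        _, _, _, s0 = small_stack(seed=4, phi0=0.0)
        _, _, _, s1 = small_stack(seed=4, phi0=0.7)
        m0 = demodulate(complex_signal(phase_differences(s0, 0)))
        m1 = demodulate(complex_signal(phase_differences(s1, 0)))
        assert np.abs(m0 - m1).max() < 1e-6 * m0.max()


class TestDemodulate:
    def test_pointwise_modulus(self):
        field = ComplexField(np.array([[3.0 - 4.0j]]), 0)
        assert demodulate(field)[0, 0] == pytest.approx(5.0)

    def test_matches_fft_oracle(self):
        phantom, psf, cfg, stack = small_stack(seed=5)
        ours = demodulate(complex_signal(phase_differences(stack, 0)))
        oracle = fft_demodulation_oracle(phantom.density, psf, cfg,
                                         cfg.thetas_deg[0])
        assert np.abs(ours - oracle).max() < 1e-6 * oracle.max()

    def test_nonfinite_field_raises(self):
        with pytest.raises(ValueError, match="finite"):
            demodulate(ComplexField(np.array([[np.nan + 0j]]), 0))


class TestCombine:
    def test_triple_copy_sums(self):
        x = np.random.default_rng(0).uniform(0, 1, (8, 8))
        sr = combine_orientations([x, x, x])
        np.testing.assert_allclose(sr.data, 3 * x)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        imgs = [rng.uniform(0, 1, (8, 8)) for _ in range(3)]
        a = combine_orientations(imgs)
        b = combine_orientations(imgs[::-1])
        np.testing.assert_allclose(a.data, b.data)

    def test_single_image_passthrough(self):
        x = np.random.default_rng(2).uniform(0, 1, (8, 8))
        np.testing.assert_array_equal(combine_orientations([x]).data, x)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            combine_orientations([])


class TestReconstruct:
    def test_zero_phantom_with_background_gives_zero(self, psf_small):
        from sdsim.simulate import IlluminationConfig, acquire_stack

        ph = make_phantom("custom", 32, SMALL["pixel_size_nm"],
                          {"density": np.zeros((32, 32))})
        cfg = IlluminationConfig(k0_cycles_per_px=0.1)
        stack = acquire_stack(ph, psf_small, cfg, b_out=0.9)
        sr = reconstruct(stack)
        assert np.allclose(sr.data, 0, atol=1e-12)

    def test_background_invariance_constant_and_smooth(self):
        """The phase-pair differencing cancels any out-of-focus background,
        the optical-sectioning mechanism of the differential method."""
        phantom, psf, cfg, stack = small_stack(seed=6)
        base = reconstruct(stack).data
        gy, gx = np.mgrid[0:32, 0:32].astype(float)
        smooth = 0.4 + 0.2 * np.sin(gx / 10.0) * np.cos(gy / 13.0)
        for b in (1.3, smooth):
            shifted_stack = small_stack(seed=6)[3]
            shifted_stack.frames = shifted_stack.frames + b
            rel = np.abs(reconstruct(shifted_stack).data - base).max() / base.max()
            assert rel < 1e-9

    def test_scale_equivariance(self):
        _, _, _, stack = small_stack(seed=7)
        base = reconstruct(stack).data
        stack.frames = 3.0 * stack.frames
        np.testing.assert_allclose(reconstruct(stack).data, 3.0 * base,
                                   rtol=1e-12)

    def test_linear_in_modulation_depth(self):
        _, _, _, lo = small_stack(seed=8, m=0.4)
        _, _, _, hi = small_stack(seed=8, m=0.8)
        a, b = reconstruct(hi).data, 2.0 * reconstruct(lo).data
        assert np.abs(a - b).max() < 1e-9 * b.max()

    def test_phi0_invariance_full_pipeline(self):
        _, _, _, s0 = small_stack(seed=9, phi0=0.0)
        _, _, _, s1 = small_stack(seed=9, phi0=0.7)
        a, b = reconstruct(s0).data, reconstruct(s1).data
        assert np.abs(a - b).max() < 1e-6 * a.max()

    def test_normalized_output_range(self):
        _, _, _, stack = small_stack(seed=10)
        sr = reconstruct(stack, normalize=True)
        assert sr.data.min() >= 0.0 and sr.data.max() <= 1.0
        assert sr.provenance["clip_percentile"] == 99.9

    def test_oracle_equivalence_many_random_phantoms(self):
        """Spatial-domain modulus vs frequency-domain oracle on 20 random
        32x32 noiseless phantoms."""
        worst = 0.0
        for seed in range(20):
            phantom, psf, cfg, stack = small_stack(seed=seed)
            ours = demodulate(complex_signal(phase_differences(stack, 0)))
            oracle = fft_demodulation_oracle(phantom.density, psf, cfg,
                                             cfg.thetas_deg[0])
            worst = max(worst, np.abs(ours - oracle).max() / oracle.max())
        assert worst < 1e-6


class TestFrequencyDomainReference:
    def test_phase_matrix_separation_is_exact(self):
        """Phases {0, pi/2, pi} give a well-conditioned band-separation matrix;
        re-mixing the separated bands reproduces the spectra."""
        _, _, cfg, stack = small_stack(seed=11)
        mat = np.array([[1.0, 0.5 * np.exp(-1j * p), 0.5 * np.exp(1j * p)]
                        for p in cfg.phases_rad])
        cond = np.linalg.cond(mat)
        assert np.isfinite(cond)
        spectra = np.stack([np.fft.fft2(stack.frames[0, j]) for j in range(3)])
        bands = np.tensordot(np.linalg.inv(mat), spectra, axes=(1, 0))
        remixed = np.tensordot(mat, bands, axes=(1, 0))
        residual = np.abs(remixed - spectra).max() / np.abs(spectra).max()
        assert residual < 1e-8

    def test_duplicate_phases_raise(self):
        _, psf, cfg, stack = small_stack(seed=11)
        stack.illumination.dphi_rad = 0.0  # all three phases identical
        with pytest.raises(ValueError, match="singular"):
            fdr_reference(stack, psf)

    def test_unmodulated_stack_reduces_to_wiener_widefield(self):
        """With m = 0 the side bands vanish and the output is the
        Wiener-filtered widefield image."""
        _, psf, cfg, stack = small_stack(seed=12, m=0.0)
        out = fdr_reference(stack, psf, wiener_w=0.15).data
        # independent Wiener filter of the widefield image
        from sdsim.reconstruct import _shifted_otf

        n = stack.shape[0]
        t0 = _shifted_otf(psf, n, 0.0, 0.0)
        est = (np.conj(t0) * np.fft.fft2(stack.widefield) * 3.0
               / (3.0 * np.abs(t0) ** 2 + 0.15 ** 2))
        fy = np.fft.fftfreq(n)
        fxg, fyg = np.meshgrid(fy, fy)
        kmax = psf.cutoff_cycles_per_px + cfg.k0_cycles_per_px
        est *= np.clip(1.0 - np.hypot(fxg, fyg) / kmax, 0.0, None)
        expected = np.clip(np.fft.ifft2(est).real, 0.0, None)
        r = np.corrcoef(out.ravel(), expected.ravel())[0, 1]
        assert r > 0.99

    def test_agrees_with_spatial_method_on_beads(self, bead_setup):
        phantom, psf, cfg, stack = bead_setup
        dm = reconstruct(stack, normalize=True).data
        fdr = fdr_reference(stack, psf)
        hi = np.percentile(fdr.data, 99.9)
        fd = np.clip(fdr.data / hi, 0, 1)
        r = np.corrcoef(dm.ravel(), fd.ravel())[0, 1]
        assert r > 0.8
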