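"""Spatial-domain reconstruction of pi/2 phase-shifted SIM stacks.

For each fringe orientation the three phase-stepped frames (phases
phi0, phi0 + pi/2, phi0 + pi) are reduced to two difference images

    d12 = D_{i,1} - D_{i,2},    d23 = D_{i,2} - D_{i,3},

which cancels the out-of-focus background exactly (optical sectioning).
Because the phase step is pi/2 the two differences are in quadrature, so

    z = d12 - i * d23 = sqrt(2) * m * I0 * [S(r) e^{i(2 pi k0.r + phi0 - pi/4)}] (x) H

is an analytic signal whose modulus |z| removes both the fringe carrier and
the (unknown) global phase phi0.  Note the prefactor: the
trigonometric identity cos x + sin x = sqrt(2) cos(x - pi/4) fixes the
constant to sqrt(2)*m*I0; all constant factors cancel under normalization.

The per-orientation modulus images are summed into the final reconstruction.
A metadata-driven frequency-domain reconstructor (band separation + Wiener
filter) is provided as an independent cross-check; it is not a parameter
estimation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import AcquisitionStack, IlluminationConfig, PSFKernel

__all__ = [
    "DifferencePair",
    "ComplexField",
    "SRImage",
    "phase_differences",
    "complex_signal",
    "demodulate",
    "combine_orientations",
    "reconstruct",
    "fdr_reference",
]


@dataclass
class DifferencePair:
    """Background-free difference images of neighbouring phase steps."""

    d12: np.ndarray
    d23: np.ndarray
    orientation_index: int

    def __post_init__(self) -> None:
        self.d12 = np.asarray(self.d12, dtype=float)
        self.d23 = np.asarray(self.d23, dtype=float)
        if self.d12.shape != self.d23.shape:
            raise ValueError("difference images must share the stack's shape")


@dataclass
class ComplexField:
    """Analytic signal z = d12 - i*d23 for one fringe orientation."""

    z: np.ndarray
    orientation_index: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=complex)


@dataclass
class SRImage:
    """Reconstructed image: nonnegative, same grid as the raw frames."""

    data: np.ndarray
    pixel_size_nm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("SR image values must be nonnegative")


def phase_differences(stack: AcquisitionStack, orientation_index: int) -> DifferencePair:
    """Subtract neighbouring phase-shifted frames of one orientation.

    Any contribution that is common to the three frames -- in particular the
    out-of-focus background, constant or spatially varying -- cancels exactly.
    """
    if not 0 <= orientation_index < stack.frames.shape[0]:
        raise ValueError(
            f"stack has no orientation {orientation_index}; "
            f"available: 0..{stack.frames.shape[0] - 1}"
        )
    if stack.frames.shape[1] != 3:
        missing = [(orientation_index, j) for j in range(stack.frames.shape[1], 3)]
        raise ValueError(f"missing phase frames {missing} for the pi/2-step pipeline")
    d1, d2, d3 = stack.frames[orientation_index]
    return DifferencePair(d1 - d2, d2 - d3, orientation_index)


def complex_signal(pair: DifferencePair) -> ComplexField:
    """Assemble the analytic signal z = d12 - i*d23."""
    return ComplexField(pair.d12 - 1j * pair.d23, pair.orientation_index)


def demodulate(field: ComplexField) -> np.ndarray:
    """Demodulated envelope |z|: removes the fringe carrier and global phase."""
    if not np.all(np.isfinite(field.z)):
        raise ValueError("complex field contains non-finite values")
    return np.abs(field.z)


def combine_orientations(images: list[np.ndarray],
                         pixel_size_nm: float = 1.0,
                         provenance: dict | None = None) -> SRImage:
    """Elementwise sum of the per-orientation demodulated images."""
    if len(images) == 0:
        raise ValueError("need at least one orientation image to combine")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError("orientation images must share a common shape")
    total = np.sum([np.asarray(im, dtype=float) for im in images], axis=0)
    prov = dict(provenance or {})
    prov.setdefault("algorithm", "spatial_difference_modulus")
    prov["n_orientations"] = len(images)
    return SRImage(total, pixel_size_nm, prov)


def reconstruct(stack: AcquisitionStack, normalize: bool = False,
                clip_percentile: float = 99.9) -> SRImage:
    """Full spatial-domain pipeline: differences -> analytic signal -> modulus
    per orientation, then orientation sum.

    ``normalize=True`` rescales the output to [0, 1] by clipping at the given
    percentile (recorded in provenance); the library default is off so scale
    equivariance is preserved.
    """
    per_orientation = []
    for i in range(stack.frames.shape[0]):
        pair = phase_differences(stack, i)
        per_orientation.append(demodulate(complex_signal(pair)))
    prov = {
        "algorithm": "spatial_difference_modulus",
        "phase_step_rad": stack.illumination.dphi_rad,
        "thetas_deg": list(stack.illumination.thetas_deg),
        "normalized": bool(normalize),
    }
    sr = combine_orientations(per_orientation, stack.pixel_size_nm, prov)
    if normalize:
        hi = np.percentile(sr.data, clip_percentile)
        if hi > 0:
            sr.data = np.clip(sr.data / hi, 0.0, 1.0)
        sr.provenance["clip_percentile"] = clip_percentile
    return sr


# ---------------------------------------------------------------------------
# frequency-domain reference (independent cross-check)


def _shifted_otf(psf: PSFKernel, n: int, k0x: float, k0y: float) -> np.ndarray:
    """OTF sampled at frequencies (f - k0) on the n x n FFT grid.

    Evaluated as a separable generalized DFT of the kernel so sub-pixel shifts
    are exact; centering at the kernel's middle pixel makes the unshifted OTF
    real for a centro-symmetric kernel.
    """
    kern = psf.kernel
    s = kern.shape[0]
    ctr = s // 2
    offs = np.arange(s, dtype=float) - ctr
    fy = np.fft.fftfreq(n) - k0y
    fx = np.fft.fftfreq(n) - k0x
    ay = np.exp(-2j * np.pi * np.outer(fy, offs))  # (n, s)
    ax = np.exp(-2j * np.pi * np.outer(fx, offs))
    return ay @ kern @ ax.T  # rows index fy, columns fx


def fdr_reference(stack: AcquisitionStack, psf: PSFKernel,
                  cfg: IlluminationConfig | None = None,
                  wiener_w: float = 0.15, apodize: bool = True) -> SRImage:
    """Frequency-domain reconstruction with known fringe parameters.

    Per orientation the three phase-stepped spectra are unmixed with the
    phase matrix rows [1, 1/2 e^{-i phi_j}, 1/2 e^{+i phi_j}], the side bands
    are recentred by exact sub-pixel phase ramps, and all bands from all
    orientations are combined with a generalized Wiener filter of parameter
    ``wiener_w``. A triangle apodization to the extended cutoff kc + k0
    (``apodize``, on by default) suppresses the ringing a hard Wiener edge
    would produce. Fringe frequency, orientations and phases come from the
    acquisition metadata; nothing is estimated from the data.
    """
    cfg = cfg or stack.illumination
    n = stack.shape[0]
    phases = cfg.phases_rad
    mat = np.array([
        [1.0, 0.5 * np.exp(-1j * p), 0.5 * np.exp(1j * p)] for p in phases
    ])
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError("phase matrix is singular (duplicate phases?)")
    inv = np.linalg.inv(mat)

    gy, gx = np.mgrid[0:n, 0:n].astype(float)
    numerator = np.zeros((n, n), dtype=complex)
    denominator = np.zeros((n, n))
    i0, m, k0 = cfg.i0, cfg.m, cfg.k0_cycles_per_px

    for i, theta_deg in enumerate(cfg.thetas_deg):
        theta = np.deg2rad(theta_deg)
        k0x, k0y = k0 * np.cos(theta), k0 * np.sin(theta)
        spectra = np.stack([np.fft.fft2(stack.frames[i, j]) for j in range(3)])
        bands = np.tensordot(inv, spectra, axes=(1, 0))  # C0, C+, C-
        c0, cp, cm = bands

        ramp = np.exp(2j * np.pi * (k0x * gx + k0y * gy))
        cp_s = np.fft.fft2(np.fft.ifft2(cp) * ramp)        # holds s(k) h(k - k0)
        cm_s = np.fft.fft2(np.fft.ifft2(cm) * np.conj(ramp))  # holds s(k) h(k + k0)

        t0 = i0 * _shifted_otf(psf, n, 0.0, 0.0)
        tp = i0 * m * _shifted_otf(psf, n, k0x, k0y)
        tm = i0 * m * _shifted_otf(psf, n, -k0x, -k0y)

        numerator += np.conj(t0) * c0 + np.conj(tp) * cp_s + np.conj(tm) * cm_s
        denominator += np.abs(t0) ** 2 + np.abs(tp) ** 2 + np.abs(tm) ** 2

    estimate = numerator / (denominator + wiener_w ** 2)
    if apodize:
        fy = np.fft.fftfreq(n)
        fxg, fyg = np.meshgrid(fy, fy)
        kmax = psf.cutoff_cycles_per_px + k0
        estimate *= np.clip(1.0 - np.hypot(fxg, fyg) / kmax, 0.0, None)
    out = np.fft.ifft2(estimate).real
    np.clip(out, 0.0, None, out=out)
    prov = {
        "algorithm": "frequency_domain_wiener",
        "wiener_w": wiener_w,
        "phases_rad": [float(p) for p in phases],
        "thetas_deg": list(cfg.thetas_deg),
        "phase_matrix_cond": float(cond),
    }
    return SRImage(out, stack.pixel_size_nm, prov)
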