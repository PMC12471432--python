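"""Forward simulation of structured-illumination fluorescence acquisition.

The forward model is the standard linear-SIM image formation: a fluorophore
density S(r) is excited by a sinusoidal fringe pattern

    I_{theta,phi}(r) = I0 * [1 + m * cos(2*pi*k0.(cos t, sin t) . r + phi)],

the emitted light is blurred by the system PSF H(r), and an out-of-focus
background B_out is added:

    D_{theta,phi}(r) = [I_{theta,phi}(r) * S(r)] (x) H(r) + B_out.

Nine raw frames (three fringe orientations, three phases stepped by pi/2) plus
a uniform-illumination widefield reference are produced per acquisition.

Coordinate convention: 0-based pixel indices, origin at the top-left corner,
``x`` is the column index and ``y`` the row index; ``k0`` is expressed in
cycles/pixel and the fringe wave vector is ``k0 * (cos(theta), sin(theta))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "Phantom",
    "PSFKernel",
    "IlluminationConfig",
    "NoiseModel",
    "AcquisitionStack",
    "make_phantom",
    "make_psf",
    "make_illumination",
    "acquire_stack",
    "convolve_psf",
]

PHANTOM_KINDS = ("beads", "line_pair", "texture", "custom")


@dataclass
class Phantom:
    """Ground-truth fluorophore density on a square, even-sized pixel grid."""

    density: np.ndarray
    pixel_size_nm: float
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 2 or self.density.shape[0] != self.density.shape[1]:
            raise ValueError("phantom density must be a square 2-D grid")
        if self.density.shape[0] % 2 != 0:
            raise ValueError("phantom grid size must be even")
        if np.any(self.density < 0):
            raise ValueError("phantom density must be nonnegative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def size_px(self) -> int:
        return self.density.shape[0]


@dataclass
class PSFKernel:
    """Discrete point spread function and its nominal frequency cutoff.

    ``cutoff_cycles_per_px`` is the incoherent OTF cutoff 2*NA/lambda converted
    to cycles/pixel.
    """

    kernel: np.ndarray
    pixel_size_nm: float
    model: str
    wavelength_nm: float
    na: float
    cutoff_cycles_per_px: float

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 2 or self.kernel.shape[0] != self.kernel.shape[1]:
            raise ValueError("PSF kernel must be square")
        if self.kernel.shape[0] % 2 != 1:
            raise ValueError("PSF kernel size must be odd (centered)")
        if np.any(self.kernel < 0):
            raise ValueError("PSF kernel must be nonnegative")
        if abs(self.kernel.sum() - 1.0) > 1e-9:
            raise ValueError("PSF kernel must sum to 1 within 1e-9")

    @property
    def size_px(self) -> int:
        return self.kernel.shape[0]

    @property
    def half_width(self) -> int:
        return self.kernel.shape[0] // 2

    def nominal_fwhm_nm(self) -> float:
        """Theoretical lateral FWHM 0.51*lambda/NA in nanometres."""
        return 0.51 * self.wavelength_nm / self.na


@dataclass
class IlluminationConfig:
    """Sinusoidal fringe parameters: mean intensity, modulation, frequency.

    Phases per orientation are ``phi0 + j*dphi`` for j = 0, 1, 2 with the
    phase step fixed at pi/2 (the quadrature stepping the reconstruction
    relies on).
    """

    k0_cycles_per_px: float
    i0: float = 1.0
    m: float = 0.9
    thetas_deg: Sequence[float] = (0.0, 60.0, 120.0)
    phi0_rad: float = 0.0
    dphi_rad: float = math.pi / 2

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("mean intensity i0 must be positive")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(
                "modulation depth m must be in [0, 1]; values outside give "
                "negative illumination intensities"
            )
        if self.k0_cycles_per_px <= 0:
            raise ValueError("k0_cycles_per_px must be positive")
        self.thetas_deg = tuple(float(t) for t in self.thetas_deg)
        if len(self.thetas_deg) == 0:
            raise ValueError("at least one fringe orientation is required")

    @property
    def phases_rad(self) -> tuple[float, float, float]:
        return tuple(self.phi0_rad + j * self.dphi_rad for j in range(3))

    @property
    def n_orientations(self) -> int:
        return len(self.thetas_deg)


@dataclass
class NoiseModel:
    """Detection noise: ``none``, additive ``gaussian``, or ``poisson_gaussian``
    (shot noise on a photon-scaled signal followed by Gaussian read noise)."""

    model: str = "none"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")


@dataclass
class AcquisitionStack:
    """The 9 raw frames D_{i,j}(r), a widefield reference and metadata."""

    frames: np.ndarray  # (n_orientations, 3, N, N)
    widefield: np.ndarray
    b_out: float | np.ndarray
    noise: NoiseModel
    illumination: IlluminationConfig
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[1] != 3:
            raise ValueError("frames must have shape (n_orientations, 3, N, N)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0] * self.frames.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[2:]

    def frame(self, orientation: int, phase: int) -> np.ndarray:
        return self.frames[orientation, phase]


# ---------------------------------------------------------------------------
# phantoms


def _render_disc(grid_y: np.ndarray, grid_x: np.ndarray, cy: float, cx: float,
                 radius: float, amplitude: float) -> np.ndarray:
    # anti-aliased disc: per-pixel coverage approximated by a linear edge ramp
    dist = np.hypot(grid_y - cy, grid_x - cx)
    return amplitude * np.clip(radius - dist + 0.5, 0.0, 1.0)


def make_phantom(kind: str, size_px: int, pixel_size_nm: float,
                 params: dict | None = None, seed: int | None = None) -> Phantom:
    """Generate a ground-truth phantom.

    Kinds: ``beads`` (anti-aliased discs emulating sub-diffraction fluorescent
    microspheres), ``line_pair`` (two one-pixel ridges at a given separation),
    ``texture`` (smooth nonnegative random field) and ``custom`` (caller
    supplies ``params['density']``).
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if size_px < 32 or size_px % 2 != 0:
        raise ValueError("size_px must be even and >= 32")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    gy, gx = np.mgrid[0:size_px, 0:size_px].astype(float)
    meta: dict = {"seed": seed, **params}

    if kind == "beads":
        n = int(params.get("n", 8))
        amplitude = float(params.get("amplitude", 1.0))
        if "radius_px" in params:
            radius = float(params["radius_px"])
        else:
            diameter_nm = float(params.get("bead_diameter_nm", 200.0))
            radius = diameter_nm / 2.0 / pixel_size_nm
            if 2 * radius < 1.0:
                raise ValueError(
                    "bead diameter is below one pixel; use a finer pixel_size_nm"
                )
        if 2 * radius < 1.0:
            raise ValueError(
                "bead diameter is below one pixel; use a finer pixel_size_nm"
            )
        margin = float(params.get("margin_px", max(16.0, radius + 8.0)))
        min_sep = float(params.get("min_separation_px", 6 * radius + 4))
        if size_px - 2 * margin <= 0:
            raise ValueError("beads do not fit inside the grid with this margin")
        centers = params.get("centers")
        if centers is None:
            centers = []
            attempts = 0
            while len(centers) < n and attempts < 20000:
                p = rng.uniform(margin, size_px - margin, 2)
                if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in centers):
                    centers.append(p)
                attempts += 1
            if len(centers) < n:
                raise ValueError("could not place beads; reduce n or min separation")
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        density = np.zeros((size_px, size_px))
        for cy, cx in centers:
            density += _render_disc(gy, gx, cy, cx, radius, amplitude)
        meta.update(centers=centers, radius_px=radius, amplitude=amplitude)
        return Phantom(density, pixel_size_nm, kind, meta)

    if kind == "line_pair":
        separation = int(params.get("separation_px", 8))
        amplitude = float(params.get("amplitude", 1.0))
        c0 = size_px // 2 - separation // 2
        c1 = c0 + separation
        if not (0 < c0 and c1 < size_px - 1):
            raise ValueError("line pair does not fit inside the grid")
        density = np.zeros((size_px, size_px))
        density[:, c0] = amplitude
        density[:, c1] = amplitude
        meta.update(columns=(c0, c1), separation_px=separation)
        return Phantom(density, pixel_size_nm, kind, meta)

    if kind == "texture":
        sigma = float(params.get("smooth_px", 4.0))
        from scipy.ndimage import gaussian_filter

        noise = rng.standard_normal((size_px, size_px))
        density = gaussian_filter(noise, sigma)
        density -= density.min()
        peak = density.max()
        if peak > 0:
            density /= peak
        density *= float(params.get("amplitude", 1.0))
        return Phantom(density, pixel_size_nm, kind, meta)

    # custom
    density = np.asarray(params["density"], dtype=float)
    return Phantom(density, pixel_size_nm, kind, meta)


# ---------------------------------------------------------------------------
# PSF


def _gaussian_energy_fraction(half_width_px: float, sigma_px: float) -> float:
    a = (half_width_px + 0.5) / (sigma_px * math.sqrt(2.0))
    return float(special.erf(a) ** 2)


def _airy_encircled_energy(radius_nm: float, wavelength_nm: float, na: float) -> float:
    # encircled energy of the Airy pattern: E(v) = 1 - J0(v)^2 - J1(v)^2
    v = 2.0 * math.pi * na * radius_nm / wavelength_nm
    return float(1.0 - special.j0(v) ** 2 - special.j1(v) ** 2)


def make_psf(model: str = "gaussian", wavelength_nm: float = 470.0, na: float = 0.6,
             pixel_size_nm: float = 30.0, size_px: int = 33,
             min_energy: float | None = None) -> PSFKernel:
    """Build a normalized PSF kernel.

    The ``gaussian`` model has FWHM = 0.51*lambda/NA exactly; the ``airy``
    model is the squared first-order jinc pattern (first zero at 0.61*lambda/NA),
    truncated to the kernel support and renormalized. The cutoff frequency is
    2*NA/lambda in both cases.

    ``min_energy`` guards against a support too small for the model's energy;
    its default is model-aware (0.99 for gaussian, 0.80 for airy, whose slowly
    decaying rings put 99% of the energy only at a ~60x larger radius than the
    first zero).
    """
    if model not in ("gaussian", "airy"):
        raise ValueError(f"unknown PSF model {model!r}")
    if na <= 0 or na > 1.5:
        raise ValueError("na must be in (0, 1.5]")
    if wavelength_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("wavelength_nm and pixel_size_nm must be positive")
    if size_px % 2 != 1:
        raise ValueError("size_px must be odd so the kernel is centered")

    half = size_px // 2
    coords = np.arange(size_px, dtype=float) - half
    X, Y = np.meshgrid(coords, coords)
    r_px = np.hypot(X, Y)

    if model == "gaussian":
        fwhm_nm = 0.51 * wavelength_nm / na
        sigma_px = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / pixel_size_nm
        kernel = np.exp(-(r_px ** 2) / (2.0 * sigma_px ** 2))
        energy = _gaussian_energy_fraction(half, sigma_px)
        threshold = 0.99 if min_energy is None else min_energy
    else:
        v = 2.0 * math.pi * na * (r_px * pixel_size_nm) / wavelength_nm
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = np.where(v == 0, 1.0, 2.0 * special.j1(v) / np.where(v == 0, 1.0, v))
        kernel = amp ** 2
        energy = _airy_encircled_energy(half * pixel_size_nm, wavelength_nm, na)
        threshold = 0.80 if min_energy is None else min_energy

    if energy < threshold:
        raise ValueError(
            f"kernel support contains only {energy:.3f} of the PSF energy "
            f"(< {threshold}); increase size_px"
        )
    kernel /= kernel.sum()
    cutoff = 2.0 * na / wavelength_nm * pixel_size_nm
    return PSFKernel(kernel, pixel_size_nm, model, wavelength_nm, na, cutoff)


# ---------------------------------------------------------------------------
# illumination and acquisition


def make_illumination(theta_deg: float, phase_rad: float, cfg: IlluminationConfig,
                      size_px: int) -> np.ndarray:
    """Evaluate the sinusoidal fringe pattern on a ``size_px`` square grid."""
    theta = math.radians(theta_deg)
    gy, gx = np.mgrid[0:size_px, 0:size_px].astype(float)
    psi = 2.0 * math.pi * cfg.k0_cycles_per_px * (
        math.cos(theta) * gx + math.sin(theta) * gy
    ) + phase_rad
    return cfg.i0 * (1.0 + cfg.m * np.cos(psi))


def convolve_psf(image: np.ndarray, psf: PSFKernel,
                 boundary: str = "reflect") -> np.ndarray:
    """FFT convolution with the PSF kernel.

    ``boundary='reflect'`` (default) runs the circular convolution on a
    reflect-padded grid (pad = kernel half-width) and crops back, which avoids
    wrap-around artifacts; ``boundary='periodic'`` convolves circularly on the
    raw grid, which conserves photon sums exactly. Complex inputs are
    supported (used by the frequency-domain oracle).
    """
    if boundary not in ("reflect", "periodic"):
        raise ValueError(f"unknown boundary mode {boundary!r}")
    pad = psf.half_width if boundary == "reflect" else 0
    padded = np.pad(image, pad, mode="reflect") if pad else np.asarray(image)
    n = padded.shape[0]
    kern = np.zeros((n, padded.shape[1]), dtype=float)
    s = psf.size_px
    kern[:s, :s] = psf.kernel
    kern = np.roll(kern, (-psf.half_width, -psf.half_width), axis=(0, 1))
    out = np.fft.ifft2(np.fft.fft2(padded) * np.fft.fft2(kern))
    if not np.iscomplexobj(image):
        out = out.real
    if pad:
        out = out[pad:pad + image.shape[0], pad:pad + image.shape[1]]
    return out


def _apply_noise(frame: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.model == "none":
        return frame
    if noise.model == "gaussian":
        sigma = float(noise.params.get("sigma", 0.01))
        return frame + rng.normal(0.0, sigma, frame.shape)
    # poisson_gaussian
    photons = float(noise.params.get("photons_per_unit", 100.0))
    sigma = float(noise.params.get("read_sigma", 0.01))
    shot = rng.poisson(np.clip(frame, 0.0, None) * photons) / photons
    return shot + rng.normal(0.0, sigma, frame.shape)


def acquire_stack(phantom: Phantom, psf: PSFKernel, cfg: IlluminationConfig,
                  b_out: float | np.ndarray = 0.0,
                  noise: NoiseModel | None = None,
                  seed: int | None = None,
                  boundary: str = "reflect") -> AcquisitionStack:
    """Simulate the 9-frame acquisition plus a widefield reference.

    Each frame is ``(I_{theta,phi} * S) (x) H + B_out``; noise, if any, is
    applied last and reproducibly from ``seed`` (or ``noise.seed``).
    ``boundary`` selects the convolution boundary handling (see
    :func:`convolve_psf`).
    """
    if abs(phantom.pixel_size_nm - psf.pixel_size_nm) > 1e-9:
        raise ValueError("phantom and PSF pixel sizes differ")
    if cfg.k0_cycles_per_px > psf.cutoff_cycles_per_px * (1 + 1e-12):
        raise ValueError(
            "illumination frequency exceeds the OTF cutoff; such fringes "
            "cannot pass the low-pass optical system"
        )
    n = phantom.size_px
    if np.ndim(b_out) == 2:
        b_out = np.asarray(b_out, dtype=float)
        if b_out.shape != phantom.density.shape:
            raise ValueError("b_out map shape does not match the phantom grid")
        if np.any(b_out < 0):
            raise ValueError("b_out must be nonnegative")
    else:
        b_out = float(b_out)
        if b_out < 0:
            raise ValueError("b_out must be nonnegative")

    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if noise.seed is not None else seed)

    frames = np.empty((cfg.n_orientations, 3, n, n))
    for i, theta in enumerate(cfg.thetas_deg):
        for j, phase in enumerate(cfg.phases_rad):
            illum = make_illumination(theta, phase, cfg, n)
            frames[i, j] = convolve_psf(illum * phantom.density, psf, boundary) + b_out
    widefield = convolve_psf(cfg.i0 * phantom.density, psf, boundary) + b_out

    for i in range(frames.shape[0]):
        for j in range(3):
            frames[i, j] = _apply_noise(frames[i, j], noise, rng)
    widefield = _apply_noise(widefield, noise, rng)

    return AcquisitionStack(frames, widefield, b_out, noise, cfg, phantom.pixel_size_nm)
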