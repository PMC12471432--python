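import numpy as np
import pytest

from sdsim.simulate import (
    IlluminationConfig,
    acquire_stack,
    make_phantom,
    make_psf,
)

# Small-grid setup used by the oracle tests: 60 nm pixels keep the PSF kernel
# (17 px) and its reflect pad inside a 32 px grid with a zero margin, so the
# padded-FFT convolution, a plain circular FFT convolution and a direct
# spatial convolution all agree to machine precision.
SMALL = {"pixel_size_nm": 60.0, "psf_size_px": 17, "size_px": 32}


@pytest.fixture(scope="session")
def psf_small():
    return make_psf("gaussian", 470.0, 0.6, SMALL["pixel_size_nm"],
                    SMALL["psf_size_px"])


def random_margin_phantom(seed, size_px=SMALL["size_px"], margin=10,
                          pixel_size_nm=SMALL["pixel_size_nm"]):
    """Random nonnegative density with a zero margin wider than the PSF pad."""
    rng = np.random.default_rng(seed)
    density = np.zeros((size_px, size_px))
    inner = size_px - 2 * margin
    density[margin:margin + inner, margin:margin + inner] = rng.uniform(0, 1, (inner, inner))
    return make_phantom("custom", size_px, pixel_size_nm, {"density": density})


def small_stack(seed=0, phi0=0.0, m=1.0, b_out=0.0, k0_frac=0.66,
                thetas=(0.0, 60.0, 120.0), psf=None):
    psf = psf or make_psf("gaussian", 470.0, 0.6, SMALL["pixel_size_nm"],
                          SMALL["psf_size_px"])
    phantom = random_margin_phantom(seed)
    cfg = IlluminationConfig(
        k0_cycles_per_px=k0_frac * psf.cutoff_cycles_per_px,
        m=m, phi0_rad=phi0, thetas_deg=thetas,
    )
    stack = acquire_stack(phantom, psf, cfg, b_out=b_out)
    return phantom, psf, cfg, stack


@pytest.fixture(scope="session")
def bead_setup():
    """Standard bead calibration acquisition (200 nm beads, k0 = 0.66 kc)."""
    from sdsim.experiments import standard_bead_stack

    return standard_bead_stack(seed=1)


@pytest.fixture()
def half_dark():
    from sdsim.experiments import half_dark_fixture

    return half_dark_fixture()
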