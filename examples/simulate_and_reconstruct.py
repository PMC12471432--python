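"""Simulate a 9-frame bead acquisition and reconstruct it in the spatial domain.

Builds a 200 nm fluorescent-bead phantom (470 nm excitation, NA 0.6, 30 nm
pixels), acquires 3 orientations x 3 phases with a pi/2 phase step, runs the
difference/modulus reconstruction, and compares per-bead Gaussian-fit FWHM
against the widefield reference.
"""

import numpy as np

from sdsim.experiments import bead_resolution_experiment, standard_bead_stack
from sdsim.reconstruct import reconstruct

phantom, psf, cfg, stack = standard_bead_stack(seed=1)
sr = reconstruct(stack, normalize=True)
print(f"acquired {stack.n_frames} raw frames of {stack.shape[0]}x{stack.shape[1]} px")
print(f"fringe frequency: {cfg.k0_cycles_per_px:.4f} cycles/px "
      f"({cfg.k0_cycles_per_px / psf.cutoff_cycles_per_px:.2f} of the OTF cutoff)")

res = bead_resolution_experiment(seed=1)
print(f"widefield mean FWHM: {res['widefield_mean_fwhm_nm']:.1f} nm "
      f"(theory {res['nominal_widefield_fwhm_nm']:.1f} nm for a point)")
print(f"reconstruction mean FWHM: {res['sr_mean_fwhm_nm']:.1f} nm")
print(f"FWHM ratio widefield/reconstruction: {res['mean_ratio']:.3f}")
print("-> the modulus pipeline keeps the widefield PSF on isolated points;")
print("   its lateral gain shows up in two-point resolvability, not bead FWHM")
print("   (see line_pair_resolution.py), while its background rejection is exact.")

# background rejection: add a large out-of-focus haze to every frame
hazy = stack
hazy.frames = hazy.frames + 2.0
sr_hazy = reconstruct(hazy, normalize=True)
print(f"max |change| after adding a constant background to all frames: "
      f"{np.abs(sr_hazy.data - sr.data).max():.2e}")
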