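"""Two-point resolvability: where the spatial-domain reconstruction wins.

Simulates pairs of parallel lines at decreasing separations and measures the
valley contrast (1 - I_mid/I_peak) between them in the widefield image and in
the reconstruction.  A pair counts as resolved when the valley contrast
reaches 0.1 (a Rayleigh-like criterion).
"""

from sdsim.experiments import line_pair_resolution_experiment

res = line_pair_resolution_experiment()
print(f"{'separation (nm)':>16} {'widefield dip':>14} {'reconstruction dip':>19}")
for sep, wf, dm in zip(res["separations_nm"], res["widefield_dips"], res["sr_dips"]):
    print(f"{sep:>16.0f} {wf:>14.3f} {dm:>19.3f}")
print(f"\nsmallest resolved separation, widefield:      "
      f"{res['widefield_min_resolved_nm']:.0f} nm")
print(f"smallest resolved separation, reconstruction: "
      f"{res['sr_min_resolved_nm']:.0f} nm")
print(f"two-point resolution gain: {res['resolution_gain']:.2f} "
      f"(band-expansion bound for k0 = 0.66 kc is 1.66)")
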