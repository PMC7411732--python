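"""Monte Carlo fluence comparison of the three illumination schemes.

Simulates light delivery to a 20 mm finger-like cylinder under bright-field,
dark-field and multiangle lateral illumination (equal photon budget per
scheme) and reports the mean fluence in shallow (A), mid-depth (B) and deep
central (C) ROIs.  Runs at reduced scale (5e4 photons, 0.5 mm voxels) so it
finishes in well under a minute; the full-resolution study lives in the test
suite.
"""

import palsim as ps

res = ps.compare_illumination_schemes(
    n_photons_per_scheme=50_000, seed=7, voxel_size=0.5
)
print("mean fluence per launched photon (mm^-2):")
print(res["table"].to_string(float_format=lambda v: f"{v:.3e}"))
print()
r = res["ratios"]
print(f"deep ROI-C ratios: lateral / bright-field = {r['lateral_over_bright_C']:.2f},"
      f" lateral / dark-field = {r['lateral_over_dark_C']:.2f}")
print()
print("The lateral scheme delivers the most light to the deep interior of a")
print("target narrower than the aperture because its beams enter through the")
print("cylinder's flank, closer to the deep ROI than the top-entry schemes.")
print(f"ROI boxes (world mm): {res['roi_boxes']}")
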