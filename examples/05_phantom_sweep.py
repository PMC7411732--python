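"""Angle-resolved light delivery on the homogeneous absorbing phantom.

Runs the full chain per schedule angle (fluence -> initial pressure -> RF ->
delay-and-sum) on the 0.133 mm^-1 absorbing phantom and prints the RMS
signal amplitude and mean signal depth in the central five-element ROI.
The RMS peaks at a small interior angle (the crossing is then fully inside
the phantom at shallow, weakly attenuated depth) and the mean depth grows
monotonically as the crossing moves deeper.
"""

import palsim as ps

report, combined, envelope = ps.phantom_angle_sweep(
    n_photons_per_angle=10_000, seed=3
)
print(report.per_angle.to_string(
    index=False, float_format=lambda v: f"{v:.4f}"
))
best = report.per_angle.loc[report.per_angle["arms"].idxmax()]
print()
print(f"A_RMS peaks at theta = {best['theta_deg']:.0f} deg; the mean signal "
      "depth rises from about "
      f"{report.per_angle['mean_depth_mm'].iloc[0]:.1f} mm at 0 deg to "
      f"{report.per_angle['mean_depth_mm'].iloc[-1]:.1f} mm at 18 deg.")
print(f"combined image: {combined.values.shape[1]} x {combined.values.shape[0]} "
      "pixels (lateral x axial), coherent sum of 10 subframes")
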