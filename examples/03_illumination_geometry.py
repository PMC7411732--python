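"""Geometry of the multiangle long-axis lateral illumination.

At theta = 0 the two side beams cross exactly at the target surface on the
lateral midline; increasing theta steepens both beams so the crossing (the
focal illumination region) moves deeper while the surface entry spots slide
outward, tiling a band of the field of view.
"""

import numpy as np

import palsim as ps
from palsim.illumination import surface_footprints

proto = ps.PHANTOM_PROTOCOL
array = ps.L14_5_38
print("theta   crossing depth below surface   footprint of +x beam (mm)")
for theta in proto.angles():
    right, left = ps.build_sources("lateral", proto, array, angle=theta)
    p, d = np.array(right.position), np.array(right.direction)
    t = -p[0] / d[0]                      # beam axis reaches the midline
    crossing_depth = p[1] + t * d[1] - proto.standoff
    (lo, hi), _ = surface_footprints([right, left], proto.standoff)
    print(f"{theta:4.0f}    {crossing_depth:8.1f} mm                 "
          f"[{lo:6.2f}, {hi:6.2f}]")

print()
print("The dark-field reference: two 38 x 1.25 mm beams tilted 20 deg on the")
print("elevation sides, overlapping at the target surface; bright-field: one")
print("38 x 5 mm beam coaxial with the acoustic axis.")
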