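"""Forward-model and reconstruct a single point absorber.

Places a point source in the water standoff region, synthesizes the
128-element RF frame, beamforms it, and reports where the envelope peak
lands relative to the true position.
"""

import numpy as np

import palsim as ps
from palsim.experiments import safe_rf_duration

labels = np.zeros((160, 200, 40), dtype=np.int32)        # 40 x 50 x 10 mm
volume = ps.VoxelVolume(
    labels, 0.25, {0: ps.OpticalProperties(0.0, 0.0, 0.0, 1.37)},
    origin=(-20.0, 0.0, -5.0),
)
array = ps.L14_5_38
p0 = np.zeros(volume.shape)
p0[100, 130, 20] = 1.0
x_true = volume.voxel_centers(0)[100]
depth_true = volume.voxel_centers(1)[130] - 19.5

rf = ps.simulate_rf(p0, volume, array, safe_rf_duration(volume, array))
grid = ps.ImageGrid.for_array(array, 32.0, dx=0.1, standoff=19.5)
image = ps.das_reconstruct(rf, grid, array, aperture_half_width=32)
env = ps.envelope_image(image)
k = np.unravel_index(np.argmax(env.values), env.values.shape)

print(f"true position: x = {x_true:.3f} mm, depth = {depth_true:.3f} mm")
print(f"envelope peak: x = {grid.x_mm[k[1]]:.3f} mm, "
      f"depth = {grid.depth_mm[k[0]]:.3f} mm")
print(f"error: {abs(grid.x_mm[k[1]] - x_true) * 1e3:.0f} um lateral, "
      f"{abs(grid.depth_mm[k[0]] - depth_true) * 1e3:.0f} um axial "
      f"(pixel: {grid.dx * 1e3:.0f} x {grid.dy * 1e3:.1f} um)")
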