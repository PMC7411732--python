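"""Scene geometries: labelled voxel volumes for the simulation studies.

All scenes share one default bounding volume (89 x 60 x 30 mm at 0.25 mm
isotropic voxels, lateral x axial x elevation) filled with the water
coupling background, with the transducer face at y = 0 and the target
surface at the standoff depth.  Four target geometries are provided:

* ``slab`` — tissue filling the volume below the standoff plane (forearm
  analogue, wider than the imaging aperture);
* ``cylinder`` — axis along elevation, default diameter 20 mm (index-finger
  analogue, narrower than the aperture);
* ``torso_mask`` — an arbitrary 2-D (lateral x axial) label mask extruded
  along elevation (e.g. a segmented mouse-torso cross-section);
* ``phantom_block`` — the homogeneous 80 x 80 x 35 mm absorbing phantom
  (mu_a 0.133 mm^-1, negligible scattering), clipped to the volume.
"""

from __future__ import annotations

import numpy as np

from .tissue_optics import (
    OpticalProperties,
    TissueModel,
    WATER_BACKGROUND,
    generic_soft_tissue,
    tissue_optical_properties,
)
from .transport import VoxelVolume

__all__ = ["build_geometry", "PHANTOM_ATTENUATION", "default_volume_extent"]

#: Measured optical attenuation of the absorbing phantom, mm^-1.
PHANTOM_ATTENUATION = 0.133

TARGET = 1
BACKGROUND = 0


def default_volume_extent() -> tuple[float, float, float]:
    """Simulation volume extent (lateral, axial, elevation), mm."""
    return (89.0, 60.0, 30.0)


def _empty_volume(
    voxel_size: float, extent: tuple[float, float, float]
) -> tuple[np.ndarray, tuple[float, float, float]]:
    shape = tuple(max(1, int(round(e / voxel_size))) for e in extent)
    labels = np.zeros(shape, dtype=np.int32)
    origin = (-extent[0] / 2.0, 0.0, -extent[2] / 2.0)
    return labels, origin


def build_geometry(
    kind: str,
    *,
    voxel_size: float = 0.25,
    extent: tuple[float, float, float] | None = None,
    standoff: float = 19.5,
    wavelength_nm: float = 800.0,
    tissue: TissueModel | None = None,
    target_properties: OpticalProperties | None = None,
    diameter: float = 20.0,
    mask: np.ndarray | None = None,
    block_size: tuple[float, float, float] = (80.0, 80.0, 35.0),
    phantom_mu_a: float = PHANTOM_ATTENUATION,
) -> VoxelVolume:
    """Build a labelled scene volume (label 0 background, 1 target).

    Target optical properties default to the generic soft-tissue model
    evaluated at ``wavelength_nm`` (override with ``target_properties``);
    the phantom block instead uses a pure absorber of ``phantom_mu_a``.
    """
    extent = default_volume_extent() if extent is None else extent
    labels, origin = _empty_volume(voxel_size, extent)
    nx, ny, nz = labels.shape
    x = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    y = origin[1] + (np.arange(ny) + 0.5) * voxel_size
    z = origin[2] + (np.arange(nz) + 0.5) * voxel_size

    if kind == "slab":
        labels[:, y >= standoff, :] = TARGET
    elif kind == "cylinder":
        r = diameter / 2.0
        yc = standoff + r
        in_circle = (x[:, None] ** 2 + (y[None, :] - yc) ** 2) <= r * r
        labels[in_circle, :] = TARGET
    elif kind == "torso_mask":
        if mask is None:
            raise ValueError("torso_mask geometry needs a 2-D mask")
        mask = np.asarray(mask)
        if mask.shape != (nx, ny):
            raise ValueError(
                f"mask shape {mask.shape} does not match the (lateral, axial) "
                f"grid {(nx, ny)}"
            )
        labels[mask > 0, :] = TARGET
    elif kind == "phantom_block":
        bx, by, bz = block_size
        mx = np.abs(x) <= bx / 2.0
        my = (y >= standoff) & (y <= standoff + by)
        mz = np.abs(z) <= bz / 2.0
        labels[np.ix_(mx, my, mz)] = TARGET
    else:
        raise ValueError(f"unknown geometry kind {kind!r}")

    if kind == "phantom_block":
        target = OpticalProperties(mu_a=phantom_mu_a, mu_s=0.0, g=0.0, eta=1.37)
    elif target_properties is not None:
        target = target_properties
    else:
        model = tissue if tissue is not None else generic_soft_tissue()
        target = tissue_optical_properties(model, wavelength_nm)

    return VoxelVolume(
        labels=labels,
        voxel_size=voxel_size,
        materials={BACKGROUND: WATER_BACKGROUND, TARGET: target},
        origin=origin,
    )
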