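"""HDF5 / TIFF / PNG artifact I/O.

HDF5 is the primary round-trip format (bit-exact); 32-bit TIFF planes are
written for external viewers and masks, and log-compressed 8-bit PNG
previews (stated dynamic range, default 40 dB) for quick inspection.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .acoustics import RFFrame
from .reconstruction import ImageGrid, PAImage
from .tissue_optics import OpticalProperties
from .transport import FluenceMap, VoxelVolume

__all__ = [
    "save_fluence",
    "load_fluence",
    "save_rf",
    "load_rf",
    "save_image",
    "load_image",
    "write_tiff",
    "write_png_preview",
]


def save_fluence(path: str | Path, fm: FluenceMap) -> None:
    vol = fm.volume
    mat_idx = sorted(vol.materials)
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=fm.phi)
        f.create_dataset("absorbed", data=fm.absorbed)
        f.create_dataset("labels", data=vol.labels)
        m = f.create_group("materials")
        m.create_dataset("index", data=np.array(mat_idx))
        for name in ("mu_a", "mu_s", "g", "eta"):
            m.create_dataset(
                name, data=np.array([getattr(vol.materials[i], name) for i in mat_idx])
            )
        f.attrs["voxel_size"] = vol.voxel_size
        f.attrs["origin"] = vol.origin
        f.attrs["n_photons"] = fm.n_photons
        f.attrs["seed"] = fm.seed
        f.attrs["escaped_weight"] = fm.escaped_weight


def load_fluence(path: str | Path) -> FluenceMap:
    with h5py.File(path, "r") as f:
        m = f["materials"]
        materials = {
            int(i): OpticalProperties(
                mu_a=float(m["mu_a"][k]), mu_s=float(m["mu_s"][k]),
                g=float(m["g"][k]), eta=float(m["eta"][k]),
            )
            for k, i in enumerate(m["index"][...])
        }
        vol = VoxelVolume(
            labels=f["labels"][...],
            voxel_size=float(f.attrs["voxel_size"]),
            materials=materials,
            origin=tuple(f.attrs["origin"]),
        )
        return FluenceMap(
            volume=vol,
            phi=f["phi"][...],
            absorbed=f["absorbed"][...],
            escaped_weight=float(f.attrs["escaped_weight"]),
            n_photons=int(f.attrs["n_photons"]),
            seed=int(f.attrs["seed"]),
        )


def save_rf(path: str | Path, rf: RFFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rf.samples)
        f.attrs["sampling_rate"] = rf.sampling_rate
        f.attrs["t0"] = rf.t0
        f.attrs["angle"] = rf.angle if isinstance(rf.angle, (int, float)) else -1.0
        f.attrs["angle_label"] = str(rf.angle)
        f.attrs["seed"] = -1 if rf.seed is None else rf.seed
        f.attrs["noise_sigma"] = rf.noise_sigma


def load_rf(path: str | Path) -> RFFrame:
    with h5py.File(path, "r") as f:
        label = f.attrs["angle_label"]
        angle: float | str
        try:
            angle = float(label)
        except ValueError:
            angle = str(label)
        seed = int(f.attrs["seed"])
        return RFFrame(
            samples=f["samples"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            t0=float(f.attrs["t0"]),
            angle=angle,
            seed=None if seed < 0 else seed,
            noise_sigma=float(f.attrs["noise_sigma"]),
        )


def _grid_attrs(grid: ImageGrid) -> dict:
    return {
        "nx": grid.nx, "dx": grid.dx, "ny": grid.ny, "dy": grid.dy,
        "standoff": grid.standoff, "x_center": grid.x_center,
        "depth_min": grid.depth_min,
    }


def save_image(path: str | Path, rf_img: PAImage, env_img: PAImage | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf_img.values)
        if env_img is not None:
            f.create_dataset("envelope", data=env_img.values)
        for k, v in _grid_attrs(rf_img.grid).items():
            f.attrs[k] = v
        f.attrs["angle_label"] = str(rf_img.angle)


def load_image(path: str | Path) -> tuple[PAImage, PAImage | None]:
    with h5py.File(path, "r") as f:
        grid = ImageGrid(
            nx=int(f.attrs["nx"]), dx=float(f.attrs["dx"]),
            ny=int(f.attrs["ny"]), dy=float(f.attrs["dy"]),
            standoff=float(f.attrs["standoff"]),
            x_center=float(f.attrs["x_center"]),
            depth_min=float(f.attrs["depth_min"]),
        )
        label = str(f.attrs["angle_label"])
        try:
            angle: float | str = float(label)
        except ValueError:
            angle = label
        rf_img = PAImage(values=f["rf"][...], grid=grid, domain="rf", angle=angle)
        env = None
        if "envelope" in f:
            env = PAImage(values=f["envelope"][...], grid=grid,
                          domain="envelope", angle=angle)
    return rf_img, env


def write_tiff(path: str | Path, values: np.ndarray) -> None:
    """32-bit float TIFF plane (or stack for a 3-D array)."""
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def write_png_preview(
    path: str | Path, env_img: PAImage, dynamic_range_db: float = 40.0
) -> None:
    """Log-compressed 8-bit preview of an envelope image."""
    import imageio.v3 as iio

    if env_img.domain != "envelope":
        raise ValueError("previews are rendered from envelope images")
    v = env_img.values
    peak = v.max()
    if peak <= 0:
        img8 = np.zeros(v.shape, dtype=np.uint8)
    else:
        db = 20.0 * np.log10(np.maximum(v, peak * 1e-12) / peak)
        img8 = np.clip(
            (db + dynamic_range_db) / dynamic_range_db, 0.0, 1.0
        ) * 255.0
        img8 = img8.astype(np.uint8)
    iio.imwrite(path, img8)
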