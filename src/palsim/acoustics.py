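"""Synthetic per-element RF generation from an initial-pressure map.

The photoacoustic source term is the standard ``p0 = Gamma * mu_a * Phi``
(Grueneisen parameter times absorbed optical energy density).  Each array
element is modelled as an ideal point detector at its centre: the trace of
element ``i`` is the sum over source voxels of

    p0(v) * (r_ref / r) * w(t - r / c),

with ``r`` the voxel-to-element distance, ``r_ref = 1 mm`` spherical-
spreading reference, and ``w`` a Gaussian-windowed sinusoid at the array
centre frequency.  No element directivity, elevation focusing or acoustic
attenuation is modelled; out-of-plane clutter arises naturally from the 3-D
source geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .transport import FluenceMap, VoxelVolume

__all__ = [
    "TransducerArray",
    "RFFrame",
    "PhantomScene",
    "initial_pressure",
    "simulate_rf",
    "L14_5_38",
]


@dataclass(frozen=True)
class TransducerArray:
    """Linear array geometry and sampling.

    Frequencies in Hz, distances in mm, speed of sound in m/s.  Element
    centres are lateral offsets relative to the array centre, symmetric
    about zero with spacing equal to the pitch.
    """

    n_elements: int = 128
    aperture: float = 38.0
    center_frequency: float = 7.2e6
    sampling_rate: float = 40e6
    speed_of_sound: float = 1540.0
    fractional_bandwidth: float = 0.7

    @property
    def pitch(self) -> float:
        return self.aperture / self.n_elements

    @property
    def element_positions(self) -> np.ndarray:
        i = np.arange(self.n_elements)
        return (i - (self.n_elements - 1) / 2.0) * self.pitch

    def element_lateral_mm(self, element: int) -> float:
        """Lateral position of a 1-based element index, mm."""
        if not 1 <= element <= self.n_elements:
            raise ValueError(f"element {element} outside 1..{self.n_elements}")
        return float(self.element_positions[element - 1])


#: The default probe: 128 elements over 38 mm, 7.2 MHz, sampled at 40 MHz.
L14_5_38 = TransducerArray()


@dataclass
class RFFrame:
    """Per-element time series s(x_i, t) for one laser pulse."""

    samples: np.ndarray          # (n_elements, n_samples)
    sampling_rate: float         # Hz
    t0: float = 0.0              # s, time of the laser pulse
    angle: float | str = 0.0     # illumination angle of this subframe, deg
    seed: int | None = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_elements, n_samples)")

    @property
    def n_elements(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def __add__(self, other: "RFFrame") -> "RFFrame":
        if self.samples.shape != other.samples.shape:
            raise ValueError("frame shapes differ")
        if self.sampling_rate != other.sampling_rate or self.t0 != other.t0:
            raise ValueError("sampling grids differ")
        return RFFrame(
            samples=self.samples + other.samples,
            sampling_rate=self.sampling_rate,
            t0=self.t0,
            angle="combined" if self.angle != other.angle else self.angle,
        )


@dataclass
class PhantomScene:
    """Absorber distribution riding on a voxel volume.

    ``absorber_map`` is per-voxel mu_a in mm^-1 (what actually converts
    fluence to pressure — it may differ from the transport mu_a when a
    chromophore of interest sits in a scattering matrix); ``grueneisen`` is
    the dimensionless Grueneisen parameter, constant over the scene.
    """

    volume: VoxelVolume
    absorber_map: np.ndarray
    grueneisen: float = 1.0

    def __post_init__(self) -> None:
        self.absorber_map = np.asarray(self.absorber_map, dtype=float)
        if self.absorber_map.shape != self.volume.shape:
            raise ValueError("absorber_map shape must match the volume")
        if np.any(self.absorber_map < 0):
            raise ValueError("absorber_map must be non-negative")

    @classmethod
    def from_labels(
        cls, volume: VoxelVolume, grueneisen: float = 1.0
    ) -> "PhantomScene":
        """Absorber map taken from the volume's own material mu_a values."""
        mua, _, _ = volume.material_arrays()
        return cls(volume=volume, absorber_map=mua[volume.labels],
                   grueneisen=grueneisen)


def initial_pressure(fluence: FluenceMap, scene: PhantomScene) -> np.ndarray:
    """Per-voxel initial pressure p0 = Gamma * mu_a * Phi (arbitrary units)."""
    if fluence.phi.shape != scene.volume.shape:
        raise ValueError("fluence and scene are on different grids")
    return scene.grueneisen * scene.absorber_map * fluence.phi


@njit(cache=True)
def _rf_kernel(vox_xyz, vox_p0, elem_x, fs, c_mm_per_s, f0, sigma_t, n_samples):
    n_el = elem_x.shape[0]
    out = np.zeros((n_el, n_samples))
    half = 4.0 * sigma_t
    for v in range(vox_xyz.shape[0]):
        x = vox_xyz[v, 0]
        y = vox_xyz[v, 1]
        z = vox_xyz[v, 2]
        p0 = vox_p0[v]
        for i in range(n_el):
            ddx = x - elem_x[i]
            r = math.sqrt(ddx * ddx + y * y + z * z)
            if r < 1e-6:
                r = 1e-6
            t_arr = r / c_mm_per_s
            amp = p0 / r  # r_ref = 1 mm
            k0 = int(math.ceil((t_arr - half) * fs))
            k1 = int(math.floor((t_arr + half) * fs))
            if k0 < 0:
                k0 = 0
            if k1 >= n_samples:
                k1 = n_samples - 1
            for k in range(k0, k1 + 1):
                tau = k / fs - t_arr
                out[i, k] += amp * math.exp(
                    -0.5 * tau * tau / (sigma_t * sigma_t)
                ) * math.cos(2.0 * math.pi * f0 * tau)
    return out


def pulse_sigma(array: TransducerArray) -> float:
    """Gaussian envelope std (s) for the array's fractional bandwidth.

    Chosen so the -6 dB spectral full width equals
    ``fractional_bandwidth * center_frequency``.
    """
    b = array.fractional_bandwidth
    return math.sqrt(2.0 * math.log(2.0)) / (math.pi * b * array.center_frequency)


def simulate_rf(
    p0: np.ndarray,
    volume: VoxelVolume,
    array: TransducerArray,
    duration: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    angle: float | str = 0.0,
    p0_threshold: float = 0.0,
) -> RFFrame:
    """Forward-model one RF subframe from an initial-pressure map.

    ``p0`` lives on ``volume``'s grid; the array face is the plane y = 0
    with elements along x at z = 0.  ``duration`` (s) must cover the time
    of flight of the farthest active voxel plus the pulse tail.
    ``p0_threshold`` drops voxels below that fraction of max(p0) to bound
    the summation cost (0 keeps every nonzero voxel).
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != volume.shape:
        raise ValueError("p0 shape must match the volume")
    if np.any(p0 < 0):
        raise ValueError("p0 must be non-negative")

    thr = p0_threshold * p0.max() if p0.size and p0.max() > 0 else 0.0
    idx = np.argwhere(p0 > max(thr, 0.0))
    xs = volume.voxel_centers(0)
    ys = volume.voxel_centers(1)
    zs = volume.voxel_centers(2)
    vox_xyz = np.column_stack(
        (xs[idx[:, 0]], ys[idx[:, 1]], zs[idx[:, 2]])
    ) if idx.size else np.zeros((0, 3))
    vox_p0 = p0[idx[:, 0], idx[:, 1], idx[:, 2]] if idx.size else np.zeros(0)

    c_mm = array.speed_of_sound * 1e3  # mm/s
    sigma_t = pulse_sigma(array)
    n_samples = int(round(duration * array.sampling_rate))
    if idx.size:
        elem = array.element_positions
        r_max = np.sqrt(
            (vox_xyz[:, 0:1] - elem[None, [0, -1]]) ** 2
            + vox_xyz[:, 1:2] ** 2
            + vox_xyz[:, 2:3] ** 2
        ).max()
        t_need = r_max / c_mm + 4.0 * sigma_t
        if duration < t_need:
            raise ValueError(
                f"duration {duration:.3e} s too short; needs >= {t_need:.3e} s "
                "to cover the farthest voxel's time of flight plus pulse tail"
            )
    samples = _rf_kernel(
        vox_xyz, vox_p0, array.element_positions,
        float(array.sampling_rate), c_mm,
        float(array.center_frequency), sigma_t, n_samples,
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sigma, size=samples.shape)
    return RFFrame(
        samples=samples,
        sampling_rate=array.sampling_rate,
        angle=angle,
        seed=seed,
        noise_sigma=noise_sigma,
    )
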