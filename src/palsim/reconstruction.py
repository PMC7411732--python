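"""Delay-and-sum beamforming, coherent multiangle summation, envelope.

A pixel (x, y) of the RF-domain image is the unapodized coherent sum of the
element traces evaluated at the one-way photoacoustic time of flight

    delta(x, x_i, y) = sqrt(y_w^2 + (x - x_i)^2) / c,

over the elements within a symmetric receive aperture of half-width
``alpha`` elements around the pixel's lateral position.  Because the
operation is linear, subframes reconstructed from per-angle partial
illuminations can be added pixel-wise (coherent summation) and equal the
reconstruction of the summed RF — the wide-illumination equivalence that the
multiangle strategy relies on.  Envelope detection is the per-column
analytic-signal magnitude.

Image depth ``y`` is referenced to the target surface; the transducer
standoff is carried by the grid so world-frame delays stay correct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.signal import hilbert

from .acoustics import RFFrame, TransducerArray

__all__ = [
    "ImageGrid",
    "PAImage",
    "time_of_flight",
    "das_reconstruct",
    "coherent_sum",
    "envelope_image",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImageGrid:
    """Pixel grid of a reconstructed image.

    ``x``: lateral pixel centres, symmetric about the array centre.
    ``depth``: axial pixel centres measured from the target surface; the
    world axial coordinate of a pixel is ``standoff + depth``.
    """

    nx: int
    dx: float
    ny: int
    dy: float
    standoff: float = 19.5
    x_center: float = 0.0
    depth_min: float = 0.0

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0 or self.nx < 1 or self.ny < 1:
            raise ValueError("grid spacings and sizes must be positive")

    @classmethod
    def for_array(
        cls,
        array: TransducerArray,
        axial_extent: float,
        lateral_extent: float | None = None,
        dx: float = 0.1,
        dy: float | None = None,
        standoff: float = 19.5,
    ) -> "ImageGrid":
        """Grid spanning the aperture laterally and ``axial_extent`` mm deep.

        Default axial spacing matches one RF sample of one-way travel,
        c / f_s (0.0385 mm at 40 MHz and 1540 m/s).
        """
        lat = array.aperture if lateral_extent is None else lateral_extent
        if dy is None:
            dy = array.speed_of_sound * 1e3 / array.sampling_rate
        return cls(
            nx=int(round(lat / dx)) + 1, dx=dx,
            ny=int(round(axial_extent / dy)) + 1, dy=dy,
            standoff=standoff,
        )

    @property
    def x_mm(self) -> np.ndarray:
        return self.x_center + (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx

    @property
    def depth_mm(self) -> np.ndarray:
        return self.depth_min + np.arange(self.ny) * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx): rows are depths, columns lateral positions."""
        return (self.ny, self.nx)


@dataclass
class PAImage:
    """Reconstructed image: signed RF amplitude or non-negative envelope."""

    values: np.ndarray
    grid: ImageGrid
    domain: str = "rf"            # "rf" | "envelope"
    angle: float | str = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.domain not in ("rf", "envelope"):
            raise ValueError("domain must be 'rf' or 'envelope'")
        if self.domain == "envelope" and np.any(self.values < -1e-12):
            raise ValueError("envelope images must be non-negative")


def time_of_flight(x: float, xi: float, y: float, c: float) -> float:
    """One-way time of flight (s) from (x, y) in mm to element at xi, c in m/s."""
    if y < 0:
        raise ValueError("y must be >= 0")
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    return math.hypot(y, x - xi) * 1e-3 / c


@njit(cache=True)
def _das_kernel(samples, elem_x, fs, t0, c_mm, xs, yw, aperture_mm, nearest):
    ny = yw.shape[0]
    nx = xs.shape[0]
    n_el, n_s = samples.shape
    out = np.zeros((ny, nx))
    for j in range(nx):
        x = xs[j]
        for i in range(n_el):
            if abs(elem_x[i] - x) > aperture_mm + 1e-9:
                continue
            dx2 = (x - elem_x[i]) * (x - elem_x[i])
            for k in range(ny):
                r = math.sqrt(yw[k] * yw[k] + dx2)
                s = (r / c_mm - t0) * fs
                if nearest:
                    si = int(round(s))
                    if 0 <= si < n_s:
                        out[k, j] += samples[i, si]
                else:
                    s0 = int(math.floor(s))
                    if 0 <= s0 < n_s - 1:
                        frac = s - s0
                        out[k, j] += (
                            (1.0 - frac) * samples[i, s0] + frac * samples[i, s0 + 1]
                        )
    return out


def das_reconstruct(
    rf: RFFrame,
    grid: ImageGrid,
    array: TransducerArray,
    aperture_half_width: int = 32,
    interpolation: str = "linear",
) -> PAImage:
    """Delay-and-sum one RF subframe onto ``grid`` (RF-domain output).

    ``aperture_half_width`` is the symmetric receive aperture in elements
    (alpha); elements farther than alpha pitches from a pixel's lateral
    position do not contribute.  Delays beyond the trace contribute zero.
    ``interpolation`` is "linear" (default) or "nearest" (for cross-checks
    against sample-exact oracles).
    """
    if aperture_half_width < 1:
        raise ValueError("aperture_half_width must be >= 1")
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    if rf.n_elements != array.n_elements:
        raise ValueError("RF frame and array element counts differ")

    elem = array.element_positions
    aperture_mm = aperture_half_width * array.pitch
    xs = grid.x_mm
    empty = np.abs(elem[None, :] - xs[:, None]).min(axis=1) > aperture_mm
    if np.any(empty):
        logger.warning(
            "%d image columns have an empty receive aperture and stay zero",
            int(empty.sum()),
        )
    yw = grid.standoff + grid.depth_mm
    values = _das_kernel(
        np.ascontiguousarray(rf.samples), elem,
        float(rf.sampling_rate), float(rf.t0),
        array.speed_of_sound * 1e3, xs, yw, aperture_mm,
        interpolation == "nearest",
    )
    return PAImage(values=values, grid=grid, domain="rf", angle=rf.angle)


def coherent_sum(subframes: Sequence[PAImage]) -> PAImage:
    """Pixel-wise sum of RF-domain subframes (the multiangle final image)."""
    if not subframes:
        raise ValueError("no subframes to sum")
    ref = subframes[0]
    total = np.zeros_like(ref.values)
    for img in subframes:
        if img.domain != "rf":
            raise ValueError("coherent summation needs RF-domain subframes")
        if img.grid != ref.grid:
            raise ValueError("subframes must share one grid")
        total += img.values
    return PAImage(values=total, grid=ref.grid, domain="rf", angle="combined")


def envelope_image(img: PAImage) -> PAImage:
    """Per-column (axial) analytic-signal magnitude of an RF-domain image."""
    if img.domain != "rf":
        raise ValueError("envelope detection expects an RF-domain image")
    env = np.abs(hilbert(img.values, axis=0))
    return PAImage(values=env, grid=img.grid, domain="envelope", angle=img.angle)
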