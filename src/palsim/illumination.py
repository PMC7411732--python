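"""Illumination geometries, the multiangle schedule, and acquisition timing.

Three epi-mode illumination schemes for a linear-array photoacoustic probe
with a transparent water standoff between the transducer face and the target
surface:

* ``dark_field`` — two thin rectangular beams on the short-axis (elevation)
  sides, tilted 20 deg so they overlap at the target's upper surface;
* ``bright_field`` — one rectangular beam coaxial with acoustic detection;
* ``lateral`` — two circular beams entering from the ends of the long
  (lateral) axis, inside the imaging plane, steered over a schedule of
  angles theta_n = theta_min + n * delta_theta.

Coordinate convention used throughout the package: ``x`` lateral (mm, zero at
the array centre), ``y`` axial depth (mm, zero at the transducer face,
positive into the medium), ``z`` elevation (mm).  Angles are degrees in every
public interface and radians internally.

Lateral-beam aiming: at theta = 0 each beam is pointed at the surface point
on the lateral midline, so the two beams cross exactly at the target surface
(the focal illumination region sits on the surface).  Increasing theta
rotates each beam toward the vertical by theta, which drives the crossing —
and with it the bulk of the delivered light — deeper along the midline while
the surface entry spots slide outward toward the beam's own side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Source",
    "AcquisitionProtocol",
    "angle_schedule",
    "build_sources",
    "max_pulse_rate",
    "servo_angular_velocity",
    "frame_rate",
    "total_frames",
    "surface_footprints",
    "PHANTOM_PROTOCOL",
    "FINGER_FOREARM_PROTOCOL",
    "MOUSE_PROTOCOL",
    "DARK_FIELD_TILT_DEG",
]

#: Fixed incidence angle of the dark-field beams (degrees from the axis).
DARK_FIELD_TILT_DEG = 20.0


@dataclass(frozen=True)
class Source:
    """A collimated top-hat beam.

    ``position`` is the beam-exit centre (mm), ``direction`` a unit vector.
    Rectangular sources carry ``width``/``height`` (mm, along the two
    transverse axes returned by :meth:`frame`); circular sources carry
    ``diameter``.
    """

    kind: Literal["rect_dark_field", "rect_bright_field", "circ_lateral"]
    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    width: float | None = None
    height: float | None = None
    diameter: float | None = None
    angle: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (|d| - 1 <= 1e-9)")
        if self.kind.startswith("rect"):
            if self.width is None or self.height is None:
                raise ValueError("rectangular sources need width and height")
        elif self.diameter is None:
            raise ValueError("circular sources need a diameter")

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal transverse axes (u, v) of the exit plane.

        ``u`` is the in-plane/lateral-most axis (the ``width`` axis for
        rectangular sources), ``v = direction x u``.
        """
        d = np.asarray(self.direction, dtype=float)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(abs(d @ ref) - 1.0) < 1e-9:
            ref = np.array([0.0, 0.0, 1.0])
        u = ref - (ref @ d) * d
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multiangle acquisition parameters (Table-style protocol block)."""

    theta_min: float = 0.0          # degrees
    delta_theta: float = 2.0        # degrees
    n_steps: int = 9
    frames_per_angle: int = 2       # K
    elevation_step: float = 2.0     # mm
    n_elevation: int = 19
    laser_prf: float = 10.0         # Hz
    servo_angular_velocity: float = 5.235987755982988  # rad/s (60 deg in 0.2 s)
    standoff: float = 19.5          # mm, transducer face to target surface
    wavelength_nm: float = 720.0

    def __post_init__(self) -> None:
        if self.delta_theta <= 0:
            raise ValueError("delta_theta must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.frames_per_angle < 1:
            raise ValueError("frames_per_angle must be >= 1")

    @property
    def n_angles(self) -> int:
        return self.n_steps + 1

    def angles(self) -> list[float]:
        return angle_schedule(self.theta_min, self.delta_theta, self.n_steps)


PHANTOM_PROTOCOL = AcquisitionProtocol()
FINGER_FOREARM_PROTOCOL = AcquisitionProtocol(
    delta_theta=4.0, n_steps=4, n_elevation=9, wavelength_nm=800.0
)
MOUSE_PROTOCOL = AcquisitionProtocol(
    delta_theta=4.0, n_steps=4, n_elevation=5, wavelength_nm=800.0
)


def angle_schedule(theta_min: float, delta_theta: float, n_steps: int) -> list[float]:
    """The ordered illumination angles [theta_min, ..., theta_min + n*dtheta]."""
    if delta_theta <= 0:
        raise ValueError("delta_theta must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return [theta_min + k * delta_theta for k in range(int(n_steps) + 1)]


def servo_angular_velocity(sweep_deg: float, time_s: float) -> float:
    """Angular velocity (rad/s) for a sweep completed in a given time.

    Returned at full precision; round to two significant figures for
    reporting.
    """
    if time_s <= 0:
        raise ValueError("time must be positive")
    return math.radians(sweep_deg) / time_s


def max_pulse_rate(omega_s: float, delta_theta_deg: float) -> int:
    """Highest usable laser pulse-repetition frequency, Hz.

    The servo must complete one angle step between pulses, so
    LPRF = omega_s / delta_theta (delta_theta in radians), reported to the
    nearest integer.
    """
    if omega_s <= 0 or delta_theta_deg <= 0:
        raise ValueError("omega_s and delta_theta must be positive")
    return round(omega_s / math.radians(delta_theta_deg))


def frame_rate(laser_prf: float, n_angles: int, frames_per_angle: int) -> float:
    """Compound frames per second: LPRF / (n_angles * frames_per_angle)."""
    if laser_prf <= 0 or n_angles <= 0 or frames_per_angle <= 0:
        raise ValueError("all arguments must be positive")
    return laser_prf / (n_angles * frames_per_angle)


def total_frames(protocol: AcquisitionProtocol) -> int:
    """Total subframes of a volume acquisition: (n+1) * K * n_elevation."""
    return protocol.n_angles * protocol.frames_per_angle * protocol.n_elevation


def _unit(v: Sequence[float]) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    a = a / np.linalg.norm(a)
    return (float(a[0]), float(a[1]), float(a[2]))


def build_sources(
    scheme: Literal["dark_field", "bright_field", "lateral"],
    protocol: AcquisitionProtocol,
    transducer,
    angle: float = 0.0,
    lateral_offset: float = 0.0,
    exit_height: float = 0.0,
    fiber_diameter: float = 5.0,
) -> list[Source]:
    """Construct the beam(s) of one illumination scheme at one angle.

    ``transducer`` supplies the 38 mm aperture.  For the lateral scheme the
    beam-exit centres sit at the two ends of the aperture (plus
    ``lateral_offset``), ``exit_height`` mm above the transducer face plane;
    ``angle`` is the schedule angle theta (see module docstring for aiming).
    Dark- and bright-field geometries ignore ``angle``.
    """
    half_ap = transducer.aperture / 2.0
    standoff = protocol.standoff
    if scheme == "bright_field":
        return [
            Source(
                kind="rect_bright_field",
                position=(0.0, 0.0, 0.0),
                direction=(0.0, 1.0, 0.0),
                width=transducer.aperture,
                height=5.0,
            )
        ]
    if scheme == "dark_field":
        tilt = math.radians(DARK_FIELD_TILT_DEG)
        z_off = standoff * math.tan(tilt)
        out = []
        for s in (+1.0, -1.0):
            out.append(
                Source(
                    kind="rect_dark_field",
                    position=(0.0, 0.0, s * z_off),
                    direction=_unit((0.0, math.cos(tilt), -s * math.sin(tilt))),
                    width=transducer.aperture,
                    height=1.25,
                    angle=DARK_FIELD_TILT_DEG,
                )
            )
        return out
    if scheme == "lateral":
        x_exit = half_ap + lateral_offset
        lever = standoff + exit_height
        phi0 = math.atan2(x_exit, lever)       # aim at (0, standoff) for theta=0
        phi = phi0 - math.radians(angle)       # rotate toward vertical with theta
        out = []
        for s in (+1.0, -1.0):
            out.append(
                Source(
                    kind="circ_lateral",
                    position=(s * x_exit, -exit_height, 0.0),
                    direction=_unit((-s * math.sin(phi), math.cos(phi), 0.0)),
                    diameter=fiber_diameter,
                    angle=angle,
                )
            )
        return out
    raise ValueError(f"unknown illumination scheme {scheme!r}")


def surface_footprints(
    sources: Sequence[Source], surface_depth: float
) -> list[tuple[float, float]]:
    """Lateral extent (x_min, x_max) of each beam on the plane y = depth.

    The footprint is the exact lateral span of the (elliptical or
    parallelogram) intersection of the collimated beam with a flat surface.
    Beams travelling parallel to the surface have no footprint and raise
    ``ValueError``.
    """
    out: list[tuple[float, float]] = []
    for src in sources:
        d = np.asarray(src.direction, dtype=float)
        if abs(d[1]) < 1e-12:
            raise ValueError("beam parallel to the surface has no footprint")
        p = np.asarray(src.position, dtype=float)
        t = (surface_depth - p[1]) / d[1]
        x0 = p[0] + t * d[0]
        u, v = src.frame()
        cu = u[0] - d[0] * u[1] / d[1]
        cv = v[0] - d[0] * v[1] / d[1]
        if src.kind == "circ_lateral":
            half = (src.diameter / 2.0) * math.hypot(cu, cv)
        else:
            half = abs(cu) * src.width / 2.0 + abs(cv) * src.height / 2.0
        out.append((x0 - half, x0 + half))
    return out
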