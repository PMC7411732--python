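"""Voxel-based Monte Carlo photon transport.

Photons are launched from collimated top-hat sources, walked through a
labelled voxel grid with exact voxel-boundary (DDA) traversal between
scattering events, and absorbed continuously by weight attenuation along
each traversed segment (track-length / absorption-weighting hybrid).
Scattering free paths are sampled from the local scattering coefficient and
deflections from the Henyey–Greenstein phase function.  ``g = 1`` media
(e.g. the purely forward-scattering water background parameterization)
short-circuit to no direction change.

Fluence is tallied with the track-length estimator, per launched photon and
per mm^2:  for a segment of length ``l`` entered with weight ``w`` in a
voxel with absorption ``mu_a``,

    phi_voxel += w * (1 - exp(-mu_a l)) / mu_a        (mu_a > 0)
    phi_voxel += w * l                                 (mu_a = 0)

so that ``phi = absorbed / (mu_a * V * N)`` holds exactly wherever
``mu_a > 0``.

Photons leaving the grid are terminated and tallied to ``escaped_weight``.
Russian roulette (threshold 1e-4, survival probability 0.1) bounds path
lengths; the zero-mean roulette weight correction is folded into
``escaped_weight`` so the energy budget ``sum(absorbed) + escaped_weight = 1``
closes exactly on every run, not just in expectation.

Refraction and Fresnel reflection at interfaces are not modelled: all media
are assumed index-matched (the use case has eta = 1.37 everywhere), and a
refractive-index mismatch between materials raises ``NotImplementedError``
rather than silently proceeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .illumination import Source
from .tissue_optics import OpticalProperties

__all__ = [
    "VoxelVolume",
    "FluenceMap",
    "GeometryError",
    "run_monte_carlo",
    "sample_scattering_angle",
]

_W_MIN = 1e-4          # Russian-roulette weight threshold
_P_SURVIVE = 0.1       # Russian-roulette survival probability


class GeometryError(ValueError):
    """A source does not intersect the simulation volume."""


@dataclass
class VoxelVolume:
    """Labelled isotropic voxel grid with per-material optical properties.

    ``labels[i, j, k]`` indexes into ``materials``; axis order is
    (x lateral, y axial, z elevation).  ``origin`` maps the corner of voxel
    (0, 0, 0) to world coordinates in mm.
    """

    labels: np.ndarray
    voxel_size: float
    materials: Mapping[int, OpticalProperties]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        present = np.unique(self.labels)
        missing = [int(m) for m in present if int(m) not in self.materials]
        if missing:
            raise ValueError(f"labels {missing} have no material entry")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size for s in self.shape)

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis, mm."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def material_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (mu_a, mu_s, g) arrays indexed by material label."""
        n = max(self.materials) + 1
        mua = np.zeros(n)
        mus = np.zeros(n)
        g = np.zeros(n)
        for idx, props in self.materials.items():
            mua[idx], mus[idx], g[idx] = props.mu_a, props.mu_s, props.g
        return mua, mus, g


@dataclass
class FluenceMap:
    """Normalized Monte Carlo output on the grid it was computed on.

    ``phi`` is fluence per launched photon (mm^-2), ``absorbed`` the
    per-voxel absorbed weight fraction.  ``escaped_weight`` is the weight
    fraction that left the grid, plus the zero-mean Russian-roulette
    correction that makes ``absorbed.sum() + escaped_weight == 1`` exact.
    """

    volume: VoxelVolume
    phi: np.ndarray
    absorbed: np.ndarray
    escaped_weight: float
    n_photons: int
    seed: int

    @property
    def weight_balance(self) -> float:
        """(sum absorbed + escaped) - 1; zero up to float accumulation."""
        return float(self.absorbed.sum() + self.escaped_weight) - 1.0


def sample_scattering_angle(g: float, u: float) -> float:
    """Cosine of the Henyey–Greenstein deflection angle for uniform ``u``.

    Isotropic for g = 0 (returns 2u - 1); delta-forward for g = 1 (returns
    exactly 1, covering the forward-scattering background medium).  The
    sample mean over uniform ``u`` converges to ``g``.
    """
    if not -1.0 <= g <= 1.0:
        raise ValueError("g must lie in [-1, 1]")
    return _hg_cosine(g, u)


@njit(cache=True)
def _hg_cosine(g: float, u: float) -> float:
    if g >= 1.0:
        return 1.0
    if g <= -1.0:
        return -1.0
    if abs(g) < 1e-7:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True)
def _mc_kernel(
    labels, mat_mua, mat_mus, mat_g,
    ox, oy, oz, h,
    src_kind, src_pos, src_dir, src_u, src_v, src_a, src_b,
    n_photons, seed,
    phi, absorbed,
):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    xmax = ox + nx * h
    ymax = oy + ny * h
    zmax = oz + nz * h
    ns = src_kind.shape[0]
    escaped = 0.0

    for n in range(n_photons):
        s = n % ns
        # launch point on the exit plane, collimated direction
        if src_kind[s] == 0:  # rectangle
            a = (np.random.random() - 0.5) * src_a[s]
            b = (np.random.random() - 0.5) * src_b[s]
        else:  # circle
            r = 0.5 * src_a[s] * math.sqrt(np.random.random())
            ang = 2.0 * math.pi * np.random.random()
            a = r * math.cos(ang)
            b = r * math.sin(ang)
        px = src_pos[s, 0] + a * src_u[s, 0] + b * src_v[s, 0]
        py = src_pos[s, 1] + a * src_u[s, 1] + b * src_v[s, 1]
        pz = src_pos[s, 2] + a * src_u[s, 2] + b * src_v[s, 2]
        dx = src_dir[s, 0]
        dy = src_dir[s, 1]
        dz = src_dir[s, 2]

        # advance to the grid if launched outside (ray/AABB)
        if not (ox <= px < xmax and oy <= py < ymax and oz <= pz < zmax):
            t0 = 0.0
            t1 = 1e30
            hit = True
            for ax in range(3):
                if ax == 0:
                    p, d, lo, hi = px, dx, ox, xmax
                elif ax == 1:
                    p, d, lo, hi = py, dy, oy, ymax
                else:
                    p, d, lo, hi = pz, dz, oz, zmax
                if abs(d) < 1e-14:
                    if p < lo or p > hi:
                        hit = False
                        break
                else:
                    ta = (lo - p) / d
                    tb = (hi - p) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if (not hit) or t1 <= t0 or t1 <= 0.0:
                escaped += 1.0
                continue
            t0 += 1e-9
            px += t0 * dx
            py += t0 * dy
            pz += t0 * dz

        ix = int((px - ox) / h)
        iy = int((py - oy) / h)
        iz = int((pz - oz) / h)
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            escaped += 1.0
            continue

        w = 1.0
        tau = -math.log(1.0 - np.random.random())
        alive = True
        while alive:
            m = labels[ix, iy, iz]
            mua = mat_mua[m]
            mus = mat_mus[m]

            # distance to the nearest voxel face along the direction
            if dx > 0.0:
                tx = (ox + (ix + 1) * h - px) / dx
            elif dx < 0.0:
                tx = (ox + ix * h - px) / dx
            else:
                tx = 1e30
            if dy > 0.0:
                ty = (oy + (iy + 1) * h - py) / dy
            elif dy < 0.0:
                ty = (oy + iy * h - py) / dy
            else:
                ty = 1e30
            if dz > 0.0:
                tz = (oz + (iz + 1) * h - pz) / dz
            elif dz < 0.0:
                tz = (oz + iz * h - pz) / dz
            else:
                tz = 1e30
            tb = tx
            axis = 0
            if ty < tb:
                tb = ty
                axis = 1
            if tz < tb:
                tb = tz
                axis = 2
            if tb < 0.0:
                tb = 0.0

            if mus > 0.0:
                ts = tau / mus
            else:
                ts = 1e30
            scatter = ts < tb
            t = ts if scatter else tb

            # continuous absorption along the segment; track-length fluence
            if mua > 0.0:
                att = math.exp(-mua * t)
                dwt = w * (1.0 - att)
                absorbed[ix, iy, iz] += dwt
                phi[ix, iy, iz] += dwt / mua
                w *= att
            else:
                phi[ix, iy, iz] += w * t

            px += t * dx
            py += t * dy
            pz += t * dz

            if scatter:
                tau = -math.log(1.0 - np.random.random())
                gg = mat_g[m]
                if gg < 1.0:
                    cost = _hg_cosine(gg, np.random.random())
                    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                    phi_az = 2.0 * math.pi * np.random.random()
                    cosp = math.cos(phi_az)
                    sinp = math.sin(phi_az)
                    if abs(dz) > 0.99999:
                        dx = sint * cosp
                        dy = sint * sinp
                        dz = cost if dz > 0.0 else -cost
                    else:
                        den = math.sqrt(1.0 - dz * dz)
                        ndx = sint * (dx * dz * cosp - dy * sinp) / den + dx * cost
                        ndy = sint * (dy * dz * cosp + dx * sinp) / den + dy * cost
                        ndz = -sint * cosp * den + dz * cost
                        norm = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
                        dx = ndx / norm
                        dy = ndy / norm
                        dz = ndz / norm
            else:
                tau -= mus * t
                if tau < 0.0:
                    tau = 0.0
                if axis == 0:
                    ix += 1 if dx > 0.0 else -1
                    if ix < 0 or ix >= nx:
                        escaped += w
                        alive = False
                elif axis == 1:
                    iy += 1 if dy > 0.0 else -1
                    if iy < 0 or iy >= ny:
                        escaped += w
                        alive = False
                else:
                    iz += 1 if dz > 0.0 else -1
                    if iz < 0 or iz >= nz:
                        escaped += w
                        alive = False

            # Russian roulette with exact-budget bookkeeping
            if alive and w < _W_MIN:
                if np.random.random() < _P_SURVIVE:
                    escaped -= w * (1.0 / _P_SURVIVE - 1.0)
                    w /= _P_SURVIVE
                else:
                    escaped += w
                    alive = False

    return escaped


def _pack_sources(sources: Sequence[Source]):
    ns = len(sources)
    kind = np.zeros(ns, dtype=np.int64)
    pos = np.zeros((ns, 3))
    dvec = np.zeros((ns, 3))
    uvec = np.zeros((ns, 3))
    vvec = np.zeros((ns, 3))
    aext = np.zeros(ns)
    bext = np.zeros(ns)
    for i, s in enumerate(sources):
        pos[i] = s.position
        dvec[i] = s.direction
        u, v = s.frame()
        uvec[i] = u
        vvec[i] = v
        if s.kind.startswith("rect"):
            kind[i] = 0
            aext[i] = s.width
            bext[i] = s.height
        else:
            kind[i] = 1
            aext[i] = s.diameter
            bext[i] = s.diameter
    return kind, pos, dvec, uvec, vvec, aext, bext


def _check_sources_hit(volume: VoxelVolume, sources: Sequence[Source]) -> None:
    ox, oy, oz = volume.origin
    ex, ey, ez = volume.extent_mm
    lo = np.array([ox, oy, oz])
    hi = lo + np.array([ex, ey, ez])
    for s in sources:
        p = np.asarray(s.position, dtype=float)
        d = np.asarray(s.direction, dtype=float)
        t0, t1 = 0.0, np.inf
        ok = True
        for ax in range(3):
            if abs(d[ax]) < 1e-14:
                if p[ax] < lo[ax] or p[ax] > hi[ax]:
                    ok = False
                    break
            else:
                ta, tb = (lo[ax] - p[ax]) / d[ax], (hi[ax] - p[ax]) / d[ax]
                if ta > tb:
                    ta, tb = tb, ta
                t0, t1 = max(t0, ta), min(t1, tb)
        if not ok or t1 <= max(t0, 0.0):
            raise GeometryError(
                f"source at {s.position} (dir {s.direction}) misses the volume"
            )


def run_monte_carlo(
    volume: VoxelVolume,
    source: Source | Sequence[Source],
    n_photons: int,
    seed: int,
) -> FluenceMap:
    """Transport ``n_photons`` through ``volume`` from one or more sources.

    Multiple sources split the photon budget evenly (round-robin), which
    models simultaneous firing of both fiber terminals.  Deterministic for a
    fixed seed: two runs with identical arguments are bit-identical.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    sources = [source] if isinstance(source, Source) else list(source)
    if not sources:
        raise ValueError("at least one source required")
    _check_sources_hit(volume, sources)

    etas = {props.eta for props in volume.materials.values()}
    if len(etas) > 1:
        raise NotImplementedError(
            "refractive-index mismatch between materials is not supported "
            f"(got eta values {sorted(etas)}); all media must be index-matched"
        )
    mua, mus, g = volume.material_arrays()
    if np.any(mua < 0) or np.any(mus < 0):
        raise ValueError("negative optical coefficients")

    phi = np.zeros(volume.shape)
    absorbed = np.zeros(volume.shape)
    kind, pos, dvec, uvec, vvec, aext, bext = _pack_sources(sources)
    escaped = _mc_kernel(
        volume.labels, mua, mus, g,
        float(volume.origin[0]), float(volume.origin[1]), float(volume.origin[2]),
        float(volume.voxel_size),
        kind, pos, dvec, uvec, vvec, aext, bext,
        int(n_photons), int(seed) & 0xFFFFFFFF,
        phi, absorbed,
    )
    voxel_volume = volume.voxel_size ** 3
    phi /= voxel_volume * n_photons
    absorbed /= n_photons
    return FluenceMap(
        volume=volume,
        phi=phi,
        absorbed=absorbed,
        escaped_weight=float(escaped) / n_photons,
        n_photons=int(n_photons),
        seed=int(seed),
    )
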