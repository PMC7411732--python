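"""ROI-based quantitative analysis of fluence maps and PA images.

Implements the per-angle light-delivery statistics (RMS amplitude A_RMS and
amplitude-weighted mean axial position of the RF signal in a rectangular
ROI), envelope-domain SNR against a noise ROI, axial/lateral profiles, an
exponential attenuation fit, and box-averaged fluence for Monte Carlo
scheme comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .acoustics import TransducerArray
from .reconstruction import PAImage
from .transport import FluenceMap

__all__ = [
    "ROI",
    "MetricsReport",
    "arms",
    "mean_axial_position",
    "snr_linear",
    "snr_db",
    "axial_profile",
    "lateral_profile",
    "fit_attenuation",
    "roi_mean_fluence",
    "central_roi",
    "peripheral_rois",
    "default_mc_roi_boxes",
]


@dataclass(frozen=True)
class ROI:
    """Rectangular region: lateral [x_min, x_max] mm, depth [y_min, y_max] mm.

    Depths are surface-referenced, matching the image grid convention.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("ROI bounds must have positive extent")

    @classmethod
    def from_elements(
        cls,
        first: int,
        last: int,
        array: TransducerArray,
        y_min: float,
        y_max: float,
        label: str = "",
    ) -> "ROI":
        """ROI spanning a 1-based inclusive element range laterally."""
        if last < first:
            raise ValueError("last element must be >= first")
        half = array.pitch / 2.0
        return cls(
            x_min=array.element_lateral_mm(first) - half,
            x_max=array.element_lateral_mm(last) + half,
            y_min=y_min,
            y_max=y_max,
            label=label,
        )

    def mask(self, img: PAImage) -> np.ndarray:
        """Boolean pixel mask of the ROI on an image grid."""
        x = img.grid.x_mm
        y = img.grid.depth_mm
        mx = (x >= self.x_min) & (x <= self.x_max)
        my = (y >= self.y_min) & (y <= self.y_max)
        m = my[:, None] & mx[None, :]
        if not m.any():
            raise ValueError(f"ROI {self.label or self} has no pixels on this grid")
        return m


def central_roi(array: TransducerArray, y_max: float = 25.5) -> ROI:
    """The central five-element ROI (elements 62-66), surface to ``y_max``."""
    return ROI.from_elements(62, 66, array, 0.0, y_max, label="ROI-1")


def peripheral_rois(array: TransducerArray, y_max: float = 25.5) -> tuple[ROI, ROI]:
    """The two peripheral five-element ROIs (elements 5-9 and 119-123)."""
    return (
        ROI.from_elements(5, 9, array, 0.0, y_max, label="ROI-2"),
        ROI.from_elements(119, 123, array, 0.0, y_max, label="ROI-3"),
    )


def arms(img: PAImage, roi: ROI) -> float:
    """Root-mean-square RF amplitude over the ROI (A_RMS)."""
    vals = img.values[roi.mask(img)]
    return float(np.sqrt(np.mean(vals**2)))


def mean_axial_position(img: PAImage, roi: ROI) -> float:
    """|S|-weighted centroid of depth over the ROI, mm."""
    m = roi.mask(img)
    w = np.abs(img.values) * m
    total = w.sum()
    if total == 0:
        raise ValueError("mean axial position undefined: ROI signal is all zero")
    depth = np.broadcast_to(img.grid.depth_mm[:, None], img.values.shape)
    return float((w * depth).sum() / total)


def snr_linear(env: PAImage, signal_roi: ROI, noise_roi: ROI) -> float:
    """Mean over the signal ROI of (S_H - mean_noise) / std_noise."""
    if env.domain != "envelope":
        raise ValueError("SNR is computed on the envelope-detected image")
    noise = env.values[noise_roi.mask(env)]
    sigma = noise.std()
    if sigma == 0:
        raise ValueError("noise ROI has zero variance")
    sig = env.values[signal_roi.mask(env)]
    return float(np.mean((sig - noise.mean()) / sigma))


def snr_db(env: PAImage, signal_roi: ROI, noise_roi: ROI) -> float:
    """20*log10 of the linear SNR; -inf when the linear SNR is not positive."""
    lin = snr_linear(env, signal_roi, noise_roi)
    if lin <= 0:
        return float("-inf")
    return 20.0 * math.log10(lin)


def axial_profile(
    img: PAImage, x_min: float, x_max: float
) -> pd.DataFrame:
    """Mean |signal| vs depth, averaged over a lateral range.

    Returns a DataFrame with columns depth_mm, amplitude.
    """
    x = img.grid.x_mm
    mx = (x >= x_min) & (x <= x_max)
    if not mx.any():
        raise ValueError("empty lateral range")
    amp = np.abs(img.values[:, mx]).mean(axis=1)
    return pd.DataFrame({"depth_mm": img.grid.depth_mm, "amplitude": amp})


def lateral_profile(
    img: PAImage, y_min: float, y_max: float
) -> pd.DataFrame:
    """Mean |signal| vs lateral position, averaged over a depth range."""
    y = img.grid.depth_mm
    my = (y >= y_min) & (y <= y_max)
    if not my.any():
        raise ValueError("empty depth range")
    amp = np.abs(img.values[my, :]).mean(axis=0)
    return pd.DataFrame({"x_mm": img.grid.x_mm, "amplitude": amp})


def fit_attenuation(
    profile: pd.DataFrame, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Exponential decay rate of an amplitude-vs-depth profile, mm^-1.

    Least-squares fit of log(amplitude) against depth; the negated slope is
    the attenuation coefficient, with a t-based confidence interval from
    the slope standard error.
    """
    depth = np.asarray(profile["depth_mm"], dtype=float)
    amp = np.asarray(profile["amplitude"], dtype=float)
    if len(depth) < 5:
        raise ValueError("need at least 5 depth points")
    if np.any(amp <= 0):
        raise ValueError(
            "profile amplitudes must be positive (use an envelope or "
            "magnitude profile)"
        )
    res = stats.linregress(depth, np.log(amp))
    mu = -res.slope
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, len(depth) - 2)
    half = tcrit * res.stderr
    return float(mu), (float(mu - half), float(mu + half))


def roi_mean_fluence(
    fluence: FluenceMap,
    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
) -> float:
    """Mean fluence over voxels whose centres fall in an axis-aligned box.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)) in world mm.
    """
    vol = fluence.volume
    masks = []
    for axis in range(3):
        c = vol.voxel_centers(axis)
        lo, hi = box[axis]
        masks.append((c >= lo) & (c <= hi))
    m = (
        masks[0][:, None, None]
        & masks[1][None, :, None]
        & masks[2][None, None, :]
    )
    if not m.any():
        raise ValueError("ROI box contains no voxel centres")
    return float(fluence.phi[m].mean())


def default_mc_roi_boxes(
    surface_depth: float,
    target_depth_extent: float,
    standoff: float = 19.5,
    half_size: float = 1.0,
) -> dict[str, tuple]:
    """Default A/B/C fluence-comparison boxes for a target under the probe.

    Centred laterally and in elevation; ROI-A sits 2 mm below the target
    surface (shallow), ROI-B at mid-depth, ROI-C in the deepest central
    interior at 85% of the target's depth extent.  Boxes are cubes of side
    ``2 * half_size`` mm in world coordinates (y measured from the
    transducer face; the target surface is at ``surface_depth``).
    """
    del standoff  # the boxes are anchored to the target surface
    out = {}
    for name, frac_depth in (("A", None), ("B", 0.5), ("C", 0.85)):
        d = 2.0 if frac_depth is None else frac_depth * target_depth_extent
        yc = surface_depth + d
        out[name] = (
            (-half_size, half_size),
            (yc - half_size, yc + half_size),
            (-half_size, half_size),
        )
    return out


@dataclass
class MetricsReport:
    """Per-angle light-delivery statistics plus summary quantities."""

    per_angle: pd.DataFrame                       # theta_deg, arms, mean_depth_mm
    snr_db: dict[str, float] = field(default_factory=dict)
    attenuation: tuple[float, tuple[float, float]] | None = None
    axial_profiles: pd.DataFrame | None = None
    lateral_profiles: pd.DataFrame | None = None

    def to_csv(self, path: str | Path) -> None:
        self.per_angle.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        summary: dict = {"snr_db": self.snr_db}
        if self.attenuation is not None:
            mu, (lo, hi) = self.attenuation
            summary["attenuation_mm^-1"] = {"estimate": mu, "ci95": [lo, hi]}
        Path(path).write_text(json.dumps(summary, indent=2))
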