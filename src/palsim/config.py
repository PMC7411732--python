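"""Structured run configuration (YAML-compatible, validated, unit-suffixed).

A :class:`RunConfig` aggregates everything one pipeline run needs: scene
geometry, illumination scheme and protocol, transport, acoustics,
reconstruction and metrics parameters.  Keys carry explicit units
(``_mm``, ``_nm``, ``_deg``, ``_hz``).  Seeds are mandatory for every
stochastic stage so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .acoustics import TransducerArray
from .illumination import AcquisitionProtocol

__all__ = [
    "SceneConfig",
    "IlluminationConfig",
    "TransportConfig",
    "AcousticsConfig",
    "ReconstructionConfig",
    "MetricsConfig",
    "RunConfig",
]


class SceneConfig(BaseModel):
    kind: Literal["slab", "cylinder", "torso_mask", "phantom_block"] = "phantom_block"
    voxel_size_mm: float = Field(0.25, gt=0)
    extent_mm: tuple[float, float, float] = (89.0, 60.0, 30.0)
    standoff_mm: float = Field(19.5, ge=0)
    wavelength_nm: float = Field(800.0, gt=0)
    diameter_mm: float = Field(20.0, gt=0)
    mask_path: Optional[str] = None
    phantom_mu_a_mm: float = Field(0.133, ge=0)


class IlluminationConfig(BaseModel):
    scheme: Literal["dark_field", "bright_field", "lateral"] = "lateral"
    theta_min_deg: float = 0.0
    angle_step_deg: float = Field(2.0, gt=0)
    n_angle_steps: int = Field(9, ge=0)
    frames_per_angle: int = Field(2, ge=1)
    elevation_step_mm: float = Field(2.0, gt=0)
    n_elevation_steps: int = Field(19, ge=1)
    laser_prf_hz: float = Field(10.0, gt=0)

    def protocol(self, standoff_mm: float, wavelength_nm: float) -> AcquisitionProtocol:
        return AcquisitionProtocol(
            theta_min=self.theta_min_deg,
            delta_theta=self.angle_step_deg,
            n_steps=self.n_angle_steps,
            frames_per_angle=self.frames_per_angle,
            elevation_step=self.elevation_step_mm,
            n_elevation=self.n_elevation_steps,
            laser_prf=self.laser_prf_hz,
            standoff=standoff_mm,
            wavelength_nm=wavelength_nm,
        )


class TransportConfig(BaseModel):
    n_photons: int = Field(..., ge=1)
    seed: int = Field(..., ge=0)


class AcousticsConfig(BaseModel):
    n_elements: int = Field(128, ge=1)
    aperture_mm: float = Field(38.0, gt=0)
    center_frequency_hz: float = Field(7.2e6, gt=0)
    sampling_rate_hz: float = Field(40e6, gt=0)
    speed_of_sound_m_s: float = Field(1540.0, gt=0)
    noise_sigma: float = Field(0.0, ge=0)
    seed: int = Field(0, ge=0)
    p0_threshold: float = Field(1e-4, ge=0)

    def array(self) -> TransducerArray:
        return TransducerArray(
            n_elements=self.n_elements,
            aperture=self.aperture_mm,
            center_frequency=self.center_frequency_hz,
            sampling_rate=self.sampling_rate_hz,
            speed_of_sound=self.speed_of_sound_m_s,
        )


class ReconstructionConfig(BaseModel):
    lateral_spacing_mm: float = Field(0.1, gt=0)
    axial_spacing_mm: Optional[float] = Field(None, gt=0)  # None -> c / fs
    axial_extent_mm: float = Field(45.0, gt=0)
    aperture_half_width: int = Field(32, ge=1)


class MetricsConfig(BaseModel):
    roi_depth_max_mm: float = Field(25.5, gt=0)


class RunConfig(BaseModel):
    scene: SceneConfig = SceneConfig()
    illumination: IlluminationConfig = IlluminationConfig()
    transport: TransportConfig
    acoustics: AcousticsConfig = AcousticsConfig()
    reconstruction: ReconstructionConfig = ReconstructionConfig()
    metrics: MetricsConfig = MetricsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        """Echo the fully-resolved config (all defaults materialized)."""
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )
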