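"""Wavelength-dependent optical properties of soft tissue and coupling media.

Soft tissue is described by a power-law reduced scattering spectrum,

    mu_s'(lambda) = a * (lambda / 500 nm)^(-b),

and an absorption spectrum mixed linearly from the four dominant
near-infrared chromophores,

    mu_a = B*O*mu_a_HbO2 + B*(1-O)*mu_a_Hb + W*mu_a_water + Fa*mu_a_lipid,

where B is the blood volume fraction, O the blood oxygen saturation, W the
water content and Fa the fat content.  The coupling medium (water) is given
explicitly rather than through the mixture model.

All coefficients are in mm^-1 and wavelengths in nm.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OpticalProperties",
    "ChromophoreTable",
    "TissueModel",
    "reduced_scattering_coeff",
    "absorption_coeff",
    "scattering_from_reduced",
    "tissue_optical_properties",
    "generic_soft_tissue",
    "WATER_BACKGROUND",
    "SOFT_TISSUE_A",
    "SOFT_TISSUE_B",
    "TISSUE_G",
    "TISSUE_ETA",
]

#: Mean power-law parameters for generic soft tissue (mm^-1, dimensionless).
SOFT_TISSUE_A = 1.89
SOFT_TISSUE_B = 1.286

#: Scattering anisotropy and refractive index of generic soft tissue.
TISSUE_G = 0.95
TISSUE_ETA = 1.37

_CHROMOPHORES = ("HbO2", "Hb", "water", "lipid")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-material optical properties.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of deflection), in [-1, 1].
    eta : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    eta: float = 1.37

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"anisotropy g={self.g} outside [-1, 1]")
        if self.eta < 1.0:
            raise ValueError(f"refractive index eta={self.eta} must be >= 1")

    @property
    def reduced_scattering(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), mm^-1."""
        return self.mu_s * (1.0 - self.g)


#: Optical properties of the water coupling medium / background.
WATER_BACKGROUND = OpticalProperties(mu_a=3.5640e-5, mu_s=1.0, g=1.0, eta=1.37)


class ChromophoreTable:
    """Absorption spectra of the tissue chromophores on a wavelength grid.

    Linear interpolation between tabulated wavelengths; requesting a
    wavelength outside the tabulated range, or a chromophore missing from
    the table, raises ``LookupError``.
    """

    def __init__(self, wavelengths_nm: np.ndarray, spectra: dict[str, np.ndarray]):
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        self.spectra = {k: np.asarray(v, dtype=float) for k, v in spectra.items()}
        for name, vals in self.spectra.items():
            if vals.shape != self.wavelengths_nm.shape:
                raise ValueError(f"spectrum {name!r} length mismatch")
            if np.any(vals < 0):
                raise ValueError(f"spectrum {name!r} has negative values")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChromophoreTable":
        """Load a table from CSV with columns wavelength_nm, mu_a_<name>."""
        import pandas as pd

        raw = pd.read_csv(path, comment="#")
        if raw.columns[0] != "wavelength_nm":
            raise ValueError("first CSV column must be wavelength_nm")
        spectra = {
            c.removeprefix("mu_a_"): raw[c].to_numpy()
            for c in raw.columns[1:]
            if c.startswith("mu_a_")
        }
        return cls(raw["wavelength_nm"].to_numpy(), spectra)

    @classmethod
    def default(cls) -> "ChromophoreTable":
        """The packaged compilation (see data/chromophores.csv for provenance)."""
        ref = importlib.resources.files("palsim") / "data" / "chromophores.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def mu_a(self, chromophore: str, wavelength_nm: float) -> float:
        """Absorption coefficient of one chromophore at one wavelength, mm^-1."""
        if chromophore not in self.spectra:
            raise LookupError(f"chromophore {chromophore!r} not in table")
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not lo <= wavelength_nm <= hi:
            raise LookupError(
                f"wavelength {wavelength_nm} nm outside tabulated range "
                f"[{lo}, {hi}] nm"
            )
        return float(
            np.interp(wavelength_nm, self.wavelengths_nm, self.spectra[chromophore])
        )


@dataclass
class TissueModel:
    """Composition-based tissue model feeding the two spectral equations.

    ``a`` (mm^-1) and ``b`` set the reduced-scattering power law; the four
    volume fractions weight the chromophore absorption spectra.
    """

    a: float = SOFT_TISSUE_A
    b: float = SOFT_TISSUE_B
    B: float = 0.15
    O: float = 0.75
    W: float = 0.20
    Fa: float = 0.10
    spectra: ChromophoreTable = field(default_factory=ChromophoreTable.default)

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("scattering scale a must be >= 0")
        for name in ("B", "O", "W", "Fa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")


def generic_soft_tissue() -> TissueModel:
    """Generic soft tissue: 15% blood at 75% sO2, 20% water, 10% fat."""
    return TissueModel()


def reduced_scattering_coeff(a: float, b: float, wavelength_nm: float) -> float:
    """Power-law reduced scattering mu_s' = a * (lambda/500 nm)^(-b), mm^-1.

    Strictly decreasing in wavelength for a > 0, b > 0; equals ``a`` at the
    500 nm reference wavelength.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if a < 0:
        raise ValueError("scattering scale a must be >= 0")
    return a * (wavelength_nm / 500.0) ** (-b)


def absorption_coeff(model: TissueModel, wavelength_nm: float) -> float:
    """Mixture absorption coefficient of a :class:`TissueModel`, mm^-1."""
    s = model.spectra
    return (
        model.B * model.O * s.mu_a("HbO2", wavelength_nm)
        + model.B * (1.0 - model.O) * s.mu_a("Hb", wavelength_nm)
        + model.W * s.mu_a("water", wavelength_nm)
        + model.Fa * s.mu_a("lipid", wavelength_nm)
    )


def scattering_from_reduced(mu_s_prime: float, g: float) -> float:
    """Similarity relation mu_s = mu_s' / (1 - g).

    The transport kernel needs mu_s and g separately; the tissue model gives
    mu_s'.  ``g = 1`` has no finite mu_s for nonzero mu_s' — the purely
    forward-scattering background is parameterized with mu_s given directly.
    """
    if g >= 1.0:
        raise ValueError(
            "g = 1 (purely forward scattering) has no finite mu_s for a given "
            "mu_s'; specify mu_s directly for such media"
        )
    if mu_s_prime < 0:
        raise ValueError("mu_s_prime must be >= 0")
    return mu_s_prime / (1.0 - g)


def tissue_optical_properties(
    model: TissueModel,
    wavelength_nm: float,
    g: float = TISSUE_G,
    eta: float = TISSUE_ETA,
) -> OpticalProperties:
    """Evaluate a :class:`TissueModel` at one wavelength as bulk properties."""
    mu_sp = reduced_scattering_coeff(model.a, model.b, wavelength_nm)
    return OpticalProperties(
        mu_a=absorption_coeff(model, wavelength_nm),
        mu_s=scattering_from_reduced(mu_sp, g),
        g=g,
        eta=eta,
    )
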