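"""Tissue optics and the PDT threshold-dose model.

Photodynamic therapy (PDT) necroses tissue wherever the number of photons
absorbed by the photosensitizer per unit volume exceeds a tissue-specific
threshold ``T`` (photons/cm^3).  For a photosensitizer with molar extinction
coefficient ``eps`` (M^-1 cm^-1) present at tissue uptake ``C`` (ug of drug
per g of tissue), that photon-count threshold maps onto a threshold *fluence*

    phi_threshold = (h * c0 / lambda) * T / mu_a^PS

where ``h * c0 / lambda`` is the photon energy and
``mu_a^PS = ln(10) * eps * c_molar`` is the photosensitizer absorption
coefficient at molar concentration ``c_molar`` (uptake converted via tissue
density and molar mass).  Tissue is predicted to necrose wherever the
delivered fluence (J/mm^2) meets or exceeds ``phi_threshold``.

This module also ships a small library of published optical properties
(absorption ``mu_a``, scattering ``mu_s``, anisotropy ``g``, refractive
index ``n``) for the five tissue roles of a metastatic vertebra model
(spinal cord, bone, sclerotic/lytic metastasis, muscle) at the two
activation wavelengths of BPD-MA (verteporfin), 690 nm and 565 nm.

Canonical internal units: mm, mm^-1, J and J/mm^2.  Unit conversions happen
only at this module's boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .errors import InvalidArgumentError, NotFoundError

__all__ = [
    "PLANCK_H",
    "LIGHT_SPEED_C0",
    "BPD_MA_MOLAR_MASS",
    "PhysicalConstants",
    "OpticalProperties",
    "ThresholdParams",
    "TissueEntry",
    "TissueLibrary",
    "photon_energy",
    "threshold_fluence",
    "tissue_library",
]

#: Planck constant, J s.
PLANCK_H = 6.626e-34
#: Speed of light in vacuum, m/s.
LIGHT_SPEED_C0 = 2.998e8
#: Molar mass of BPD-MA (verteporfin), g/mol.
BPD_MA_MOLAR_MASS = 718.8

TISSUE_ROLES = ("spinal_cord", "bone", "metastasis_sclerotic", "metastasis_lytic", "muscle")
WAVELENGTHS_NM = (690, 565)


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable physical constants used by the threshold model."""

    planck_h: float = PLANCK_H
    light_speed_c0: float = LIGHT_SPEED_C0


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one tissue at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scatter angle),
        dimensionless, in [-1, 1].
    n : float
        Refractive index, dimensionless, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise InvalidArgumentError("mu_a and mu_s must be nonnegative")
        if self.mu_a + self.mu_s <= 0:
            raise InvalidArgumentError("mu_a + mu_s must be positive")
        if not -1.0 <= self.g <= 1.0:
            raise InvalidArgumentError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise InvalidArgumentError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scatter albedo mu_s / mu_t."""
        return self.mu_s / self.mu_t


@dataclass(frozen=True)
class ThresholdParams:
    """Threshold-dose parameters of one tissue at one wavelength.

    ``phi_threshold`` (J/mm^2) may be supplied directly (the library defaults
    carry published values) or computed from the photon-count threshold via
    :func:`threshold_fluence`.
    """

    T: float  # necrosis threshold, photons/cm^3
    uptake_C: float  # photosensitizer uptake, ug/g
    eps_molar: float  # molar extinction coefficient, M^-1 cm^-1
    phi_threshold: float  # threshold fluence, J/mm^2
    molar_mass: float = BPD_MA_MOLAR_MASS  # g/mol
    tissue_density: float = 1.0  # g/cm^3

    def __post_init__(self) -> None:
        for name in ("T", "uptake_C", "eps_molar", "phi_threshold", "molar_mass", "tissue_density"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TissueEntry:
    optics: OpticalProperties
    thresholds: ThresholdParams


@dataclass(frozen=True)
class TissueLibrary:
    """Per-tissue, per-wavelength optical and threshold parameters.

    Keys are ``(tissue_role, wavelength_nm)``.  A *view* for one wavelength
    and lesion type (sclerotic or lytic) is obtained with :meth:`view`, which
    maps the generic ``metastasis`` role onto the requested lesion type.
    """

    entries: Mapping[tuple[str, int], TissueEntry] = field(repr=False)

    def __post_init__(self) -> None:
        for role in TISSUE_ROLES:
            for wl in WAVELENGTHS_NM:
                if (role, wl) not in self.entries:
                    raise InvalidArgumentError(f"library incomplete: missing ({role}, {wl} nm)")

    def get(self, tissue: str, wavelength_nm: int) -> TissueEntry:
        try:
            return self.entries[(tissue, int(wavelength_nm))]
        except KeyError:
            raise NotFoundError(f"no entry for tissue {tissue!r} at {wavelength_nm} nm") from None

    def view(self, wavelength_nm: int, lesion_type: str = "sclerotic") -> dict[str, TissueEntry]:
        """Return ``{role: entry}`` for the four anatomical roles at one wavelength.

        The returned mapping uses the anatomy labels (``spinal_cord``,
        ``bone``, ``metastasis``, ``muscle``); ``metastasis`` resolves to the
        sclerotic or lytic entry.
        """
        if int(wavelength_nm) not in WAVELENGTHS_NM:
            raise NotFoundError(f"no tissue data at {wavelength_nm} nm (supported: 690, 565)")
        if lesion_type not in ("sclerotic", "lytic"):
            raise NotFoundError(f"unknown lesion type {lesion_type!r}")
        wl = int(wavelength_nm)
        return {
            "spinal_cord": self.get("spinal_cord", wl),
            "bone": self.get("bone", wl),
            "metastasis": self.get(f"metastasis_{lesion_type}", wl),
            "muscle": self.get("muscle", wl),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TissueLibrary":
        entries: dict[tuple[str, int], TissueEntry] = {}
        for role, by_wl in data["tissues"].items():
            for wl_key, rec in by_wl.items():
                wl = int(wl_key)
                optics = OpticalProperties(
                    mu_a=float(rec["mu_a"]), mu_s=float(rec["mu_s"]),
                    g=float(rec["g"]), n=float(rec["n"]),
                )
                thr = ThresholdParams(
                    T=float(rec["T"]), uptake_C=float(rec["uptake_C"]),
                    eps_molar=float(rec["eps_molar"]),
                    phi_threshold=float(rec["phi_threshold"]),
                    molar_mass=float(rec.get("molar_mass", BPD_MA_MOLAR_MASS)),
                    tissue_density=float(rec.get("tissue_density", 1.0)),
                )
                entries[(role, wl)] = TissueEntry(optics, thr)
        return cls(entries=entries)

    @classmethod
    def from_yaml(cls, path) -> "TissueLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        tissues: dict[str, dict] = {}
        for (role, wl), e in sorted(self.entries.items()):
            rec = {
                "mu_a": e.optics.mu_a, "mu_s": e.optics.mu_s,
                "g": e.optics.g, "n": e.optics.n,
                "T": e.thresholds.T, "uptake_C": e.thresholds.uptake_C,
                "eps_molar": e.thresholds.eps_molar,
                "phi_threshold": e.thresholds.phi_threshold,
                "molar_mass": e.thresholds.molar_mass,
                "tissue_density": e.thresholds.tissue_density,
            }
            tissues.setdefault(role, {})[wl] = rec
        return {"tissues": tissues}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def photon_energy(wavelength_m: float) -> float:
    """Energy of one photon, J, for a vacuum wavelength in metres."""
    if wavelength_m <= 0:
        raise InvalidArgumentError("wavelength must be positive")
    return PLANCK_H * LIGHT_SPEED_C0 / wavelength_m


def threshold_fluence(
    T: float,
    uptake_C: float,
    eps_molar: float,
    wavelength_m: float,
    molar_mass: float = BPD_MA_MOLAR_MASS,
    tissue_density: float = 1.0,
) -> float:
    """Threshold fluence (J/mm^2) from the photon-count necrosis threshold.

    Parameters
    ----------
    T : float
        Necrosis threshold, photons absorbed by the photosensitizer per cm^3.
    uptake_C : float
        Photosensitizer uptake in tissue, ug/g.
    eps_molar : float
        Molar extinction coefficient, M^-1 cm^-1, at ``wavelength_m``.
    wavelength_m : float
        Activation wavelength, m.
    molar_mass : float
        Photosensitizer molar mass, g/mol (default BPD-MA, 718.8).
    tissue_density : float
        Tissue mass density, g/cm^3, used to convert uptake to molarity.

    Notes
    -----
    The uptake is converted to molar concentration assuming the given tissue
    density; the photosensitizer absorption coefficient is
    ``mu_a^PS = ln(10) * eps * c`` (cm^-1) and the returned fluence is
    ``photon_energy * T / mu_a^PS`` converted from J/cm^2 to J/mm^2.  The
    result is linear in ``T`` and inversely proportional to ``uptake_C`` and
    ``eps_molar``.
    """
    for name, v in (("T", T), ("uptake_C", uptake_C), ("eps_molar", eps_molar),
                    ("wavelength_m", wavelength_m), ("molar_mass", molar_mass),
                    ("tissue_density", tissue_density)):
        if v <= 0:
            raise InvalidArgumentError(f"{name} must be strictly positive")
    # ug/g -> g drug per cm^3 tissue -> mol/cm^3 -> mol/L
    c_molar = uptake_C * 1e-6 * tissue_density / molar_mass * 1000.0
    mu_a_ps_cm = math.log(10.0) * eps_molar * c_molar  # cm^-1
    fluence_j_per_cm2 = photon_energy(wavelength_m) * T / mu_a_ps_cm
    return fluence_j_per_cm2 / 100.0  # J/cm^2 -> J/mm^2


def default_tissue_library() -> TissueLibrary:
    """The packaged default tissue library (published values for a
    metastatic vertebra at 690 and 565 nm)."""
    ref = resources.files("spinepdt.data").joinpath("tissues.yaml")
    with ref.open() as fh:
        return TissueLibrary.from_dict(yaml.safe_load(fh))


def tissue_library(wavelength_nm: int, lesion_type: str = "sclerotic") -> dict[str, TissueEntry]:
    """Convenience view of the default library for one wavelength/lesion type."""
    return default_tissue_library().view(wavelength_nm, lesion_type)
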