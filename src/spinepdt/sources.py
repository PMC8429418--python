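"""Interstitial light emitters: cut-end fibres and cylindrical diffusers.

Two source types are modelled as samplable emission distributions:

* A *cut-end fibre* emits from its flat tip: launch positions uniform on the
  core disc, directions uniform in solid angle within the acceptance cone of
  half-angle ``asin(NA / n_medium)`` about the fibre axis (NA is specified in
  air, so the in-tissue cone narrows with the medium's refractive index).
* A *cylindrical diffuser* emits from its lateral surface with uniform power
  per unit length and a Lambertian (cosine-weighted) direction distribution
  about the outward radial normal; the end caps do not emit.

Placement helpers reproduce the qualitative default geometry of the planning
study: four cut-end fibres inside the lesion pointing diagonally at 45 deg
away from the spinal cord, or two parallel diffusers spanning the lesion's
long axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, PlacementError
from .phantom import LabelVolume

__all__ = [
    "CutEndFibre",
    "CylindricalDiffuser",
    "IsotropicPointSource",
    "EmissionSample",
    "LesionSummary",
    "sample_emission",
    "default_configuration",
    "summarize_lesion",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidArgumentError("zero-length vector cannot be normalized")
    return v / n


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed frame."""
    a = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, helper))
    e2 = np.cross(a, e1)
    return e1, e2


@dataclass(frozen=True)
class CutEndFibre:
    """Flat-cleaved fibre tip emitting a forward cone set by its NA."""

    tip_position: tuple[float, float, float]  # mm
    axis: tuple[float, float, float]  # unit vector, emission direction
    core_radius: float = 0.2  # mm (400 um core diameter)
    numerical_aperture: float = 0.22  # in air

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", tuple(_unit(self.axis)))
        if self.core_radius <= 0:
            raise InvalidArgumentError("core_radius must be positive")
        if not 0 <= self.numerical_aperture < 10:
            raise InvalidArgumentError("numerical aperture out of range")


@dataclass(frozen=True)
class CylindricalDiffuser:
    """Cylindrical diffuser emitting radially along its length."""

    endpoint_a: tuple[float, float, float]  # mm
    endpoint_b: tuple[float, float, float]  # mm
    radius: float = 0.5  # mm

    def __post_init__(self) -> None:
        a, b = np.asarray(self.endpoint_a, float), np.asarray(self.endpoint_b, float)
        if np.linalg.norm(b - a) <= 0:
            raise InvalidArgumentError("diffuser endpoints must be distinct")
        if self.radius <= 0:
            raise InvalidArgumentError("diffuser radius must be positive")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(
            np.asarray(self.endpoint_b, float) - np.asarray(self.endpoint_a, float)))


@dataclass
class EmissionSample:
    """A batch of launch states: positions (n,3) mm, unit directions (n,3),
    statistical weights (n,) equal to 1 at launch."""

    position: np.ndarray
    direction: np.ndarray
    weight: np.ndarray


def sample_emission(source, rng: np.random.Generator, n: int = 1,
                    n_medium: float = 1.56) -> EmissionSample:
    """Draw ``n`` photon-packet launch states from a source.

    ``n_medium`` is the refractive index of the tissue at the emitting
    surface; it narrows a cut-end fibre's acceptance cone (NA is defined in
    air) and is ignored for diffusers.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if isinstance(source, CutEndFibre):
        na = source.numerical_aperture
        if na >= n_medium:
            raise InvalidArgumentError(
                f"NA ({na}) must be below the medium refractive index ({n_medium})")
        axis = np.asarray(source.axis, float)
        e1, e2 = _orthonormal_basis(axis)
        # position: uniform on the core disc
        r = source.core_radius * np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        pos = (np.asarray(source.tip_position, float)[None, :]
               + r[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
        # direction: uniform in solid angle within the cone about axis
        cos_max = math.cos(math.asin(na / n_medium))
        cos_t = 1.0 - rng.random(n) * (1.0 - cos_max)
        sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
        psi = 2 * np.pi * rng.random(n)
        dirs = (cos_t[:, None] * axis
                + sin_t[:, None] * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2))
    elif isinstance(source, CylindricalDiffuser):
        a = np.asarray(source.endpoint_a, float)
        b = np.asarray(source.endpoint_b, float)
        axis = _unit(b - a)
        e1, e2 = _orthonormal_basis(axis)
        t = rng.random(n)
        phi = 2 * np.pi * rng.random(n)
        normal = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
        pos = a[None, :] + t[:, None] * (b - a)[None, :] + source.radius * normal
        # Lambertian about the outward radial normal
        cos_t = np.sqrt(rng.random(n))
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        psi = 2 * np.pi * rng.random(n)
        tang1 = axis[None, :]
        tang2 = np.cross(normal, axis)
        dirs = (cos_t[:, None] * normal
                + sin_t[:, None] * (np.cos(psi)[:, None] * tang1 + np.sin(psi)[:, None] * tang2))
    elif isinstance(source, IsotropicPointSource):
        pos = np.broadcast_to(np.asarray(source.position, float), (n, 3)).copy()
        cos_t = 2.0 * rng.random(n) - 1.0
        sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
        psi = 2 * np.pi * rng.random(n)
        dirs = np.stack([sin_t * np.cos(psi), sin_t * np.sin(psi), cos_t], axis=1)
    else:
        raise InvalidArgumentError(f"unknown source type {type(source).__name__}")
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return EmissionSample(position=pos, direction=dirs, weight=np.ones(n))


@dataclass(frozen=True)
class IsotropicPointSource:
    """Idealized isotropic point emitter (used for transport validation
    against the diffusion-approximation closed form)."""

    position: tuple[float, float, float]  # mm


@dataclass(frozen=True)
class LesionSummary:
    """Geometry summary used to place default source configurations."""

    centroid: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # half-extent along x, y, z, mm
    toward_cord: tuple[float, float, float]  # unit vector lesion -> cord

    def __post_init__(self) -> None:
        object.__setattr__(self, "toward_cord", tuple(_unit(self.toward_cord)))


def summarize_lesion(vol: LabelVolume) -> LesionSummary:
    """Centroid, axis-aligned half-extents and cord direction of the lesion."""
    les = np.argwhere(vol.mask("metastasis"))
    crd = np.argwhere(vol.mask("spinal_cord"))
    if len(les) == 0:
        raise PlacementError("volume contains no metastasis voxels")
    if len(crd) == 0:
        raise PlacementError("volume contains no spinal cord voxels")
    sp = np.asarray(vol.spacing)
    org = np.asarray(vol.origin)
    c_les = (les.mean(axis=0) + 0.5) * sp + org
    c_crd = (crd.mean(axis=0) + 0.5) * sp + org
    half = (les.max(axis=0) - les.min(axis=0) + 1) * sp / 2.0
    return LesionSummary(centroid=tuple(c_les), semi_axes=tuple(half),
                         toward_cord=tuple(_unit(c_crd - c_les)))


def default_configuration(kind: str, lesion: LesionSummary,
                          vol: LabelVolume | None = None) -> list:
    """Default source placements for the two studied configurations.

    ``cut_end_4``: four fibre tips around the lesion centroid, each axis at
    45 deg to the anterior direction (away from the cord), diagonal in the
    plane perpendicular to the cord direction.  ``diffuser_2``: two parallel
    diffusers spanning the lesion's long axis (minus a 4 mm margin),
    symmetric about the centroid.  If ``vol`` is given, every emitter is
    checked to lie inside the metastasis label.
    """
    c = np.asarray(lesion.centroid, float)
    anterior = -np.asarray(lesion.toward_cord, float)
    e1, e2 = _orthonormal_basis(anterior)
    ax = np.asarray(lesion.semi_axes, float)
    # lesion half-extent along e1/e2 (axis-aligned approximation)
    h1 = float(np.sqrt(np.sum((ax * e1) ** 2)))
    h2 = float(np.sqrt(np.sum((ax * e2) ** 2)))

    sources: list = []
    if kind == "cut_end_4":
        s45, c45 = math.sin(math.pi / 4), math.cos(math.pi / 4)
        for sgn1 in (-1.0, 1.0):
            for sgn2 in (-1.0, 1.0):
                lateral = (sgn1 * e1 + sgn2 * e2) / math.sqrt(2.0)
                axis = s45 * lateral + c45 * anterior
                tip = c + 0.35 * (sgn1 * h1 * e1 + sgn2 * h2 * e2)
                sources.append(CutEndFibre(tip_position=tuple(tip), axis=tuple(axis)))
    elif kind == "diffuser_2":
        long_idx = int(np.argmax(ax))
        e_long = np.zeros(3)
        e_long[long_idx] = 1.0
        if abs(float(np.dot(e_long, lesion.toward_cord))) > 0.9:
            raise PlacementError("lesion long axis points at the cord; "
                                 "supply explicit diffuser endpoints")
        length = 2.0 * ax[long_idx] - 4.0
        if length <= 0:
            raise PlacementError("lesion too small for the default diffuser length")
        # offset perpendicular to both the long axis and the cord direction
        e_off = _unit(np.cross(e_long, lesion.toward_cord))
        off_half = ax[int(np.argmax(np.abs(e_off)))]
        for sgn in (-1.0, 1.0):
            center = c + sgn * 0.3 * off_half * e_off
            a = center - 0.5 * length * e_long
            b = center + 0.5 * length * e_long
            sources.append(CylindricalDiffuser(endpoint_a=tuple(a), endpoint_b=tuple(b)))
    else:
        raise InvalidArgumentError(f"unknown configuration kind {kind!r}")

    if vol is not None:
        met = vol.mask("metastasis")
        sp = np.asarray(vol.spacing)
        org = np.asarray(vol.origin)

        def _inside(p) -> bool:
            idx = np.floor((np.asarray(p) - org) / sp).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.asarray(met.shape)):
                return False
            return bool(met[tuple(idx)])

        for s in sources:
            pts = ([s.tip_position] if isinstance(s, CutEndFibre)
                   else [s.endpoint_a, s.endpoint_b,
                         tuple((np.asarray(s.endpoint_a) + np.asarray(s.endpoint_b)) / 2)])
            for p in pts:
                if not _inside(p):
                    raise PlacementError(
                        f"{type(s).__name__} emitter point {tuple(round(float(x), 2) for x in p)} "
                        "lies outside the metastasis")
    return sources
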