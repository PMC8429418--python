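"""Voxel Monte Carlo photon transport and fluence kernels.

Each interstitial source is characterised by a *fluence kernel*: the
per-voxel fluence delivered per unit emitted energy (mm^-2, i.e. J/mm^2 of
fluence per J launched).  Because light transport is linear in the source
power, any treatment plan's dose map is a nonnegative linear combination of
kernels, which is what makes LP-based power allocation possible.

The transport model is standard weighted-packet Monte Carlo on the labelled
voxel grid: exponential free paths with the local interaction coefficient,
Henyey-Greenstein scattering, weight attenuation by the single-scatter
albedo, track-length fluence scoring, unpolarized Fresnel
reflection/refraction at voxel faces where the refractive index changes
(including tissue-air at the outer boundary), and Russian roulette for low
weights.  A diffusion-approximation closed form for an isotropic point
source in a homogeneous medium is provided as an independent oracle.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import _mckernel
from .errors import InvalidArgumentError, NotFoundError, PlacementError
from .optics import OpticalProperties, TissueEntry
from .phantom import LABELS, LabelVolume
from .sources import (CutEndFibre, CylindricalDiffuser, IsotropicPointSource,
                      sample_emission)

__all__ = [
    "RNGSpec",
    "FluenceKernel",
    "hg_sample",
    "fresnel_reflectance",
    "diffusion_point_source",
    "simulate_kernel",
    "write_kernel",
    "read_kernel",
]

#: Packet weight below which Russian roulette is played.
ROULETTE_THRESHOLD = 1e-4
#: Roulette survival probability (survivors carry 1/p times the weight).
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class RNGSpec:
    """Reproducible random-stream specification.

    The same spec (algorithm, master seed, stream index) yields bit-identical
    kernels; distinct stream indices give independent kernels for multiple
    sources under one master seed.
    """

    master_seed: int
    stream: int = 0
    algorithm: str = "numba-mt19937"

    def batch_seed(self, batch: int) -> int:
        """Deterministic 31-bit transport seed for one batch."""
        return (self.master_seed * 9973 + self.stream * 7919 + batch * 1000003 + 17) % (2 ** 31)

    def emission_rng(self, batch: int) -> np.random.Generator:
        return np.random.default_rng([self.master_seed, self.stream, batch, 0xE])


@dataclass
class FluenceKernel:
    """Per-voxel fluence per unit emitted energy for one source."""

    values: np.ndarray  # (nx, ny, nz) float64, mm^-2
    rel_error: np.ndarray | None  # per-voxel relative standard error
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    n_packets: int
    rng: RNGSpec
    source: object
    wavelength_nm: int
    tallies: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


def hg_sample(g: float, u: float):
    """Henyey-Greenstein scattering-angle cosine by inverse-CDF sampling.

    ``cos(theta) = (1/2g) * [1 + g^2 - ((1 - g^2) / (1 - g + 2 g u))^2]`` for
    ``g != 0``; uniform on [-1, 1) in the isotropic limit ``g = 0``.  Accepts
    scalars or arrays of uniform variates ``u`` in [0, 1).
    """
    if not abs(g) < 1.0:
        raise InvalidArgumentError("anisotropy |g| must be < 1")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0.0) or np.any(u_arr >= 1.0):
        raise InvalidArgumentError("uniform variate u must lie in [0, 1)")
    if abs(g) < 1e-6:
        out = 2.0 * u_arr - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    return float(out) if np.isscalar(u) else out


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflection probability at a planar interface.

    Returns 1 beyond the critical angle (total internal reflection).
    """
    if n1 < 1.0 or n2 < 1.0:
        raise InvalidArgumentError("refractive indices must be >= 1")
    if not 0.0 < cos_incident <= 1.0:
        raise InvalidArgumentError("cos_incident must lie in (0, 1]")
    return float(_mckernel.fresnel_unpolarized(n1, n2, cos_incident))


def diffusion_point_source(optics: OpticalProperties, r) -> float | np.ndarray:
    """Diffusion-approximation fluence (mm^-2 per J) of an isotropic point
    source in an infinite homogeneous medium.

    ``phi(r) = exp(-mu_eff r) / (4 pi D r)`` with diffusion coefficient
    ``D = 1 / (3 (mu_a + mu_s (1 - g)))`` and ``mu_eff = sqrt(mu_a / D)``.
    Accurate only in scattering-dominated media (``mu_s' >> mu_a``); warns
    otherwise.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise InvalidArgumentError("radius must be positive")
    mu_s_red = optics.mu_s * (1.0 - optics.g)
    if mu_s_red < 10.0 * optics.mu_a:
        warnings.warn("diffusion approximation dubious: mu_s' is not >> mu_a",
                      stacklevel=2)
    D = 1.0 / (3.0 * (optics.mu_a + mu_s_red))
    mu_eff = math.sqrt(optics.mu_a / D)
    out = np.exp(-mu_eff * r_arr) / (4.0 * np.pi * D * r_arr)
    return float(out) if np.isscalar(r) else out


def _label_property_arrays(lib_view: dict[str, TissueEntry], n_outside: float):
    """Label-indexed (mu_a, mu_s, g, n) arrays; label 0 is non-scattering air."""
    n_lbl = len(LABELS)
    mu_a = np.zeros(n_lbl)
    mu_s = np.zeros(n_lbl)
    g = np.zeros(n_lbl)
    n = np.full(n_lbl, float(n_outside))
    for tissue, code in LABELS.items():
        if tissue == "outside":
            continue
        if tissue not in lib_view:
            raise NotFoundError(f"tissue library view lacks properties for {tissue!r}")
        o = lib_view[tissue].optics
        mu_a[code] = o.mu_a
        mu_s[code] = o.mu_s
        g[code] = o.g
        n[code] = o.n
    return mu_a, mu_s, g, n


def _anchor_points(source) -> list[tuple[float, float, float]]:
    if isinstance(source, CutEndFibre):
        return [source.tip_position]
    if isinstance(source, CylindricalDiffuser):
        mid = tuple((np.asarray(source.endpoint_a) + np.asarray(source.endpoint_b)) / 2.0)
        return [source.endpoint_a, source.endpoint_b, mid]
    if isinstance(source, IsotropicPointSource):
        return [source.position]
    raise InvalidArgumentError(f"unknown source type {type(source).__name__}")


def simulate_kernel(
    vol: LabelVolume,
    lib_view: dict[str, TissueEntry],
    source,
    n_packets: int,
    rng: RNGSpec,
    wavelength_nm: int = 690,
    n_outside: float = 1.0,
    n_batches: int | None = None,
) -> FluenceKernel:
    """Monte Carlo estimate of one source's fluence kernel.

    Parameters
    ----------
    vol : LabelVolume
        The labelled anatomy.
    lib_view : dict
        ``{tissue: TissueEntry}`` for the four anatomical roles at the run's
        wavelength (see :meth:`TissueLibrary.view`).
    source : CutEndFibre | CylindricalDiffuser | IsotropicPointSource
        Emitter; must lie inside labelled tissue.
    n_packets : int
        Number of photon packets (>= 1000).
    rng : RNGSpec
        Random-stream specification; identical specs give identical kernels.
    n_outside : float
        Refractive index outside the anatomy (1.0 = air; set equal to the
        tissue index to emulate matched boundaries in validation runs).
    n_batches : int, optional
        Number of statistically independent batches used for the per-voxel
        relative-standard-error map (default: 10 for >= 10^4 packets).

    Returns
    -------
    FluenceKernel
        Fluence per unit emitted energy (mm^-2) with per-voxel relative
        standard error and the weight ledger in ``tallies``.
    """
    if n_packets < 1000:
        raise InvalidArgumentError("n_packets must be >= 1000")
    labels = np.ascontiguousarray(vol.labels)
    sp = np.asarray(vol.spacing, float)
    org = np.asarray(vol.origin, float)
    for p in _anchor_points(source):
        idx = np.floor((np.asarray(p, float) - org) / sp).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(labels.shape)) \
                or labels[tuple(idx)] == 0:
            raise PlacementError(
                f"source point {tuple(round(float(x), 2) for x in p)} lies outside "
                "the labelled anatomy")
    mu_a, mu_s, g_arr, n_arr = _label_property_arrays(lib_view, n_outside)

    # refractive index at the emitting surface, for the cut-end cone angle
    tip = np.asarray(_anchor_points(source)[0], float)
    tip_idx = tuple(np.floor((tip - org) / sp).astype(int))
    n_medium = float(n_arr[labels[tip_idx]])

    if n_batches is None:
        n_batches = 10 if n_packets >= 10_000 else (4 if n_packets >= 4000 else 1)
    base = n_packets // n_batches
    batch_sizes = [base + (1 if b < n_packets % n_batches else 0) for b in range(n_batches)]

    total = np.zeros(labels.shape, dtype=np.float64)
    total_sq = np.zeros(labels.shape, dtype=np.float64) if n_batches > 1 else None
    tallies = np.zeros(3)
    for b, m in enumerate(batch_sizes):
        em = sample_emission(source, rng.emission_rng(b), n=m, n_medium=n_medium)
        batch_fl = np.zeros(labels.shape, dtype=np.float64)
        _mckernel.trace_batch(
            labels, sp[0], sp[1], sp[2], org[0], org[1], org[2],
            mu_a, mu_s, g_arr, n_arr,
            np.ascontiguousarray(em.position), np.ascontiguousarray(em.direction),
            rng.batch_seed(b), ROULETTE_THRESHOLD, ROULETTE_SURVIVAL,
            batch_fl, tallies)
        batch_fl /= m  # per launched packet
        total += batch_fl
        if total_sq is not None:
            total_sq += batch_fl ** 2

    vv = vol.voxel_volume_mm3
    mean = total / n_batches
    kernel = mean / vv  # mm^-2 per unit launched energy
    rel_err = None
    if total_sq is not None:
        var = np.maximum(total_sq / n_batches - mean ** 2, 0.0)
        se = np.sqrt(var / max(n_batches - 1, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_err = np.where(mean > 0, se / mean, 0.0).astype(np.float32)
    absorbed, escaped, roulette_net = (float(t) for t in tallies)
    return FluenceKernel(
        values=kernel, rel_error=rel_err, spacing=tuple(vol.spacing),
        origin=tuple(vol.origin), n_packets=n_packets, rng=rng, source=source,
        wavelength_nm=int(wavelength_nm),
        tallies={
            "launched": float(n_packets),
            "absorbed": absorbed,
            "escaped": escaped,
            "roulette_net": roulette_net,
        },
    )


def _source_meta(source) -> dict:
    import dataclasses
    d = {"type": type(source).__name__}
    if dataclasses.is_dataclass(source):
        d.update({f.name: getattr(source, f.name) for f in dataclasses.fields(source)})
    return d


def write_kernel(kernel: FluenceKernel, prefix) -> None:
    """Persist a kernel as NIfTI float volume plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    aff = np.diag(list(kernel.spacing) + [1.0])
    aff[:3, 3] = kernel.origin
    nib.save(nib.Nifti1Image(kernel.values.astype(np.float32), aff),
             str(prefix.with_suffix(".nii.gz")))
    meta = {
        "n_packets": kernel.n_packets,
        "wavelength_nm": kernel.wavelength_nm,
        "spacing": list(kernel.spacing),
        "origin": list(kernel.origin),
        "rng": {"master_seed": kernel.rng.master_seed, "stream": kernel.rng.stream,
                "algorithm": kernel.rng.algorithm},
        "source": _source_meta(kernel.source),
        "tallies": kernel.tallies,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_kernel(prefix) -> FluenceKernel:
    """Load a kernel written by :func:`write_kernel` (metadata partially
    reconstructed; rel_error is not persisted)."""
    prefix = Path(prefix)
    img = nib.load(str(prefix.with_suffix(".nii.gz")))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    src_meta = meta["source"]
    cls = {"CutEndFibre": CutEndFibre, "CylindricalDiffuser": CylindricalDiffuser,
           "IsotropicPointSource": IsotropicPointSource}.get(src_meta.pop("type"))
    source = cls(**{k: tuple(v) if isinstance(v, list) else v
                    for k, v in src_meta.items()}) if cls else None
    return FluenceKernel(
        values=np.asarray(img.dataobj, dtype=np.float64),
        rel_error=None,
        spacing=tuple(meta["spacing"]), origin=tuple(meta["origin"]),
        n_packets=meta["n_packets"],
        rng=RNGSpec(master_seed=meta["rng"]["master_seed"], stream=meta["rng"]["stream"],
                    algorithm=meta["rng"]["algorithm"]),
        source=source, wavelength_nm=meta["wavelength_nm"], tallies=meta["tallies"])
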