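"""Synthetic labelled voxel phantoms of a metastatically involved vertebra.

Patient CT segmentations are not redistributable, so every downstream stage
(transport, planning, reporting) is exercised on a parametric stand-in: an
elliptic-cylinder vertebral body of bone containing an ellipsoidal
metastatic lesion, a cylindrical spinal cord in a posterior canal, and
muscle filling the remainder of an outer elliptic-cylinder boundary.
Primitive scales are adjusted by monotone bisection so the achieved
per-tissue volumes match a target specification (default: the case-1-like
volumes of 23.21 / 4.72 / 31.14 / 171.84 cm^3 for metastasis / cord / bone /
muscle).

Coordinate convention: right-handed, +y = posterior (toward the cord),
+z = superior; voxel centers at ``origin + (i + 0.5) * spacing``; labels are
voxel-center assignments (no partial volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InfeasibleSpecError, ValidationError

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "LabelVolume",
    "PhantomSpec",
    "build_vertebra_phantom",
    "tissue_volumes",
    "read_label_volume",
    "write_label_volume",
]

#: Tissue label codes.  0 is reserved for air outside the anatomy.
LABELS = {"outside": 0, "muscle": 1, "bone": 2, "metastasis": 3, "spinal_cord": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class LabelVolume:
    """Integer-labelled 3D voxel raster with physical spacing (mm)."""

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    spacing: tuple[float, float, float]  # mm per voxel axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive on all axes")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers, mm."""
        return tuple(
            self.origin[a] + (np.arange(self.labels.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABELS[tissue]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic vertebra phantom.

    ``target_volumes_cm3`` are matched within ``volume_tol`` (relative) by
    scaling the geometric primitives; the remaining fields fix the anatomy's
    proportions and relative placement.  Construction is deterministic for a
    fixed ``rng_seed`` (the seed only matters when ``jitter_mm > 0``).
    """

    target_volumes_cm3: dict = field(default_factory=lambda: {
        "metastasis": 23.21, "spinal_cord": 4.72, "bone": 31.14, "muscle": 171.84,
    })
    height_mm: float = 50.0            # phantom (and cord/muscle) axial extent
    body_height_mm: float = 30.0       # vertebral-body axial extent
    body_axis_ratio: float = 1.1       # lateral/AP semi-axis ratio of the body
    lesion_axis_ratios: tuple[float, float, float] = (1.0, 0.75, 0.58)
    lesion_offset_mm: tuple[float, float, float] = (0.0, 3.5, 0.0)  # from body center
    canal_offset_mm: float = 29.4      # body center -> cord center, posterior
    outer_axis_ratio: float = 1.15     # AP/lateral semi-axis ratio of muscle boundary
    lesion_type: str = "sclerotic"
    pitch_mm: float = 1.0
    volume_tol: float = 0.02
    breach: bool = False               # allow lesion to touch the canal
    jitter_mm: float = 0.0             # Gaussian surface jitter amplitude
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.target_volumes_cm3.items():
            if k != "metastasis" and v <= 0:
                raise InfeasibleSpecError(f"target volume for {k} must be positive")
            if v < 0:
                raise InfeasibleSpecError(f"target volume for {k} must be nonnegative")
        if self.pitch_mm <= 0:
            raise InfeasibleSpecError("voxel pitch must be positive")
        if self.lesion_type not in ("sclerotic", "lytic"):
            raise InfeasibleSpecError(f"unknown lesion type {self.lesion_type!r}")

    @classmethod
    def case1(cls, pitch_mm: float = 1.0, **kwargs) -> "PhantomSpec":
        """The default case-1-like specification at the given voxel pitch."""
        return cls(pitch_mm=pitch_mm, **kwargs)


def _bisect_volume(count_fn, target_mm3: float, lo: float, hi: float, what: str,
                   tol: float, iters: int = 48) -> float:
    """Find scale s in [lo, hi] with count_fn(s) ~ target by bisection.

    ``count_fn`` returns achieved volume in mm^3 and is nondecreasing in s.
    Raises if the target is outside the reachable range or the relative
    error of the best iterate exceeds ``tol``.
    """
    v_lo, v_hi = count_fn(lo), count_fn(hi)
    if target_mm3 < v_lo or target_mm3 > v_hi:
        raise InfeasibleSpecError(
            f"{what}: target {target_mm3 / 1000:.2f} cm^3 outside achievable range "
            f"[{v_lo / 1000:.2f}, {v_hi / 1000:.2f}] cm^3 (limiting dimension: {what})")
    best_s, best_err = lo, abs(v_lo - target_mm3)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        v = count_fn(mid)
        if abs(v - target_mm3) < best_err:
            best_s, best_err = mid, abs(v - target_mm3)
        if v < target_mm3:
            lo = mid
        else:
            hi = mid
    if best_err / target_mm3 > tol:
        raise InfeasibleSpecError(
            f"{what}: best achievable volume misses target by "
            f"{100 * best_err / target_mm3:.1f}% (> {100 * tol:.0f}%); "
            f"reduce voxel pitch or relax the spec")
    return best_s


def build_vertebra_phantom(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the phantom described by ``spec`` onto a voxel grid.

    Primitive scales (cord radius, lesion size, vertebral-body cross-section,
    outer muscle boundary) are each found by 1-D monotone bisection on the
    voxelized volume, in dependency order, so the achieved volumes match
    ``spec.target_volumes_cm3`` within ``spec.volume_tol``.
    """
    tv = {k: 1000.0 * v for k, v in spec.target_volumes_cm3.items()}  # mm^3
    p = spec.pitch_mm
    H = spec.height_mm
    vv = p * p * p

    # Initial analytic guesses for primitive sizes.
    r_cord0 = np.sqrt(tv["spinal_cord"] / (np.pi * H))
    body_target = tv["bone"] + tv["metastasis"]
    area_body = body_target / spec.body_height_mm
    body_a0 = np.sqrt(area_body * spec.body_axis_ratio / np.pi)
    body_b0 = body_a0 / spec.body_axis_ratio
    outer_target = tv["muscle"] + body_target + tv["spinal_cord"]
    area_outer = outer_target / H
    outer_a0 = np.sqrt(area_outer / (np.pi * spec.outer_axis_ratio))
    outer_b0 = outer_a0 * spec.outer_axis_ratio

    # Grid sized to the largest plausible outer boundary plus one-voxel margin.
    ext_x = 1.3 * outer_a0 + p
    ext_y = max(1.3 * outer_b0, spec.canal_offset_mm + 3 * r_cord0) + p
    nx = int(np.ceil(2 * ext_x / p))
    ny = int(np.ceil(2 * ext_y / p))
    nz = int(np.ceil(H / p))
    origin = (-nx * p / 2.0, -ny * p / 2.0, -H / 2.0)

    xs = origin[0] + (np.arange(nx) + 0.5) * p
    ys = origin[1] + (np.arange(ny) + 0.5) * p
    zs = origin[2] + (np.arange(nz) + 0.5) * p
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    rng = np.random.default_rng(spec.rng_seed)
    if spec.jitter_mm > 0:
        jitter = rng.normal(0.0, spec.jitter_mm, size=X.shape)
    else:
        jitter = 0.0

    in_slab = np.abs(Z) <= spec.body_height_mm / 2.0

    # 1. Spinal cord: cylinder at (0, canal_offset), full height.
    cy = spec.canal_offset_mm

    def cord_mask(r):
        return (X ** 2 + (Y - cy) ** 2) <= r ** 2

    r_cord = _bisect_volume(lambda r: vv * np.count_nonzero(cord_mask(r)),
                            tv["spinal_cord"], 0.3 * r_cord0, 2.5 * r_cord0,
                            "spinal cord radius", spec.volume_tol)
    cord = cord_mask(r_cord)

    # 2. Lesion: ellipsoid offset from body center, scale s on all semi-axes.
    la, lb, lc = spec.lesion_axis_ratios
    ox, oy, oz = spec.lesion_offset_mm

    def lesion_mask(s):
        if s <= 0:
            return np.zeros_like(X, dtype=bool)
        q = (((X - ox) / (s * la)) ** 2 + ((Y - oy) / (s * lb)) ** 2
             + ((Z - oz) / (s * lc)) ** 2)
        return q + jitter / max(s, 1e-9) <= 1.0

    if tv["metastasis"] > 0:
        s_guess = (tv["metastasis"] / (4.0 / 3.0 * np.pi * la * lb * lc)) ** (1.0 / 3.0)
        s_les = _bisect_volume(lambda s: vv * np.count_nonzero(lesion_mask(s)),
                               tv["metastasis"], 0.3 * s_guess, 1.8 * s_guess,
                               "lesion size", spec.volume_tol)
        lesion = lesion_mask(s_les)
    else:
        s_les = 0.0
        lesion = np.zeros_like(X, dtype=bool)

    # 3. Vertebral body: elliptic cylinder; bone = body minus lesion minus cord.
    def body_mask(t):
        e = ((X / (t * body_a0)) ** 2 + ((Y) / (t * body_b0)) ** 2)
        return (e + jitter <= 1.0) & in_slab

    def bone_vol(t):
        m = body_mask(t)
        return vv * np.count_nonzero(m & ~lesion & ~cord)

    t_body = _bisect_volume(bone_vol, tv["bone"], 0.5, 2.0,
                            "vertebral body cross-section", spec.volume_tol)
    body = body_mask(t_body)
    if not spec.breach and tv["metastasis"] > 0 and np.any(lesion & ~body):
        raise InfeasibleSpecError(
            "lesion size: lesion extends outside the vertebral body "
            "(limiting dimension: vertebral body semi-axes); enlarge the body "
            "or reduce the lesion offset")

    # 4. Outer muscle boundary: muscle = outer minus body minus cord.
    def outer_mask(u):
        return ((X / (u * outer_a0)) ** 2 + (Y / (u * outer_b0)) ** 2) <= 1.0

    def muscle_vol(u):
        m = outer_mask(u)
        return vv * np.count_nonzero(m & ~body & ~cord & ~lesion)

    u_outer = _bisect_volume(muscle_vol, tv["muscle"], 0.6, 1.6,
                             "outer muscle boundary", spec.volume_tol)
    outer = outer_mask(u_outer)

    labels = np.zeros(X.shape, dtype=np.uint8)
    labels[outer] = LABELS["muscle"]
    labels[body] = LABELS["bone"]
    labels[lesion] = LABELS["metastasis"]
    labels[cord] = LABELS["spinal_cord"]

    vol = LabelVolume(labels=labels, spacing=(p, p, p), origin=origin)
    # Lesion/cord adjacency guard (face adjacency) unless a breach is requested.
    if not spec.breach and tv["metastasis"] > 0:
        les = vol.mask("metastasis")
        crd = vol.mask("spinal_cord")
        grown = np.zeros_like(les)
        for ax in range(3):
            for sh in (-1, 1):
                grown |= np.roll(les, sh, axis=ax)
        if np.any(grown & crd):
            raise InfeasibleSpecError(
                "canal offset: lesion is adjacent to the spinal cord but the "
                "breach flag is not set (limiting dimension: canal offset)")
    return vol


def tissue_volumes(vol: LabelVolume) -> dict[str, float]:
    """Per-tissue volume in cm^3 (voxel count x voxel volume)."""
    vv = vol.voxel_volume_mm3
    counts = np.bincount(vol.labels.ravel(), minlength=len(LABELS))
    return {
        LABEL_NAMES[code]: counts[code] * vv / 1000.0
        for code in range(len(LABELS))
        if counts[code] > 0
    }


def _affine(vol: LabelVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a label volume as NIfTI (spacing and origin in the affine)."""
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), _affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label_volume(path) -> LabelVolume:
    """Read a NIfTI label volume; validates spacing metadata and label codes."""
    path = Path(path)
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: missing or nonpositive voxel spacing in header")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim} dimensions")
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{path}: non-integer label values present")
        arr = np.round(arr).astype(np.int64)
    bad = arr > max(LABELS.values())
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValidationError(
            f"{path}: unknown label code {int(arr[idx])} at voxel index {idx}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelVolume(labels=arr.astype(np.uint8), spacing=zooms, origin=origin)
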