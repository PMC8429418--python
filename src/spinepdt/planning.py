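"""Per-source energy allocation by convex optimization under the PDT
threshold-dose model.

Because fluence is linear in each source's emitted energy, the dose map of a
plan with energies ``E_j`` is ``d = sum_j E_j k_j`` for fluence kernels
``k_j``, and power allocation reduces to a linear program.  Two planning
modes are provided:

* *coverage* — an inner LP minimizes a weighted sum of one-sided penalties
  (organ-at-risk overdose above each tissue's threshold fluence plus
  tumour-weighted underdose below the tumour threshold) over ``E >= 0``; an
  outer monotone bisection on the tumour weight drives the achieved tumour
  coverage into a target band (default: at least 90% of tumour voxels at or
  above threshold).  Among iterates meeting the target, the plan with the
  least spinal-cord damage (then least total energy) is returned; if the
  achieved coverage still overshoots the band, all energies are scaled down
  uniformly until coverage just meets the target (no gratuitous overdose).
* *sparing* — maximizes a concave coverage surrogate
  ``sum_i min(d_i, phi_tumour)`` subject to hard per-voxel constraints
  keeping every spinal-cord voxel strictly below its threshold (palliative
  mode: no cord necrosis by construction).

Degenerate optima (e.g. mirror-symmetric geometries) are resolved by tiny
lexicographic tie-break terms preferring first a lower total energy and then
a lower peak per-source energy; the latter also reflects per-fibre power
limits in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps
from scipy.optimize import linprog

from .errors import IncompatibleKernelsError, InvalidArgumentError, NotFoundError
from .optics import TissueEntry
from .phantom import LabelVolume
from .transport import FluenceKernel

__all__ = [
    "PlanConfig",
    "Plan",
    "DoseMap",
    "superpose_dose",
    "optimize_coverage",
    "optimize_sparing",
]


@dataclass
class PlanConfig:
    """Planning-mode parameters.

    ``target_coverage`` is the tumour voxel fraction to reach at threshold in
    coverage mode; the tumour weight is adjusted automatically within
    ``[tumour_weight_min, tumour_weight_max]``.  ``oar_weights`` scale the
    per-tissue overdose penalties.  ``max_lp_voxels`` caps the number of
    voxels per tissue entering the LP (uniform stride subsampling); achieved
    coverage and damage are always recomputed on the full grid.
    """

    mode: str = "coverage"  # "coverage" | "sparing"
    target_coverage: float = 0.9
    coverage_tol: float = 0.002
    tumour_weight: float | None = None  # fixed weight; None = auto bisection
    tumour_weight_min: float = 1e-3
    tumour_weight_max: float = 1e6
    oar_weights: dict = field(default_factory=lambda: {
        "spinal_cord": 1.0, "bone": 0.05, "muscle": 0.05})
    cord_constraint: str = "hard"  # sparing mode: "hard" | "soft"
    soft_cord_weight: float = 1e4
    max_iterations: int = 30
    max_lp_voxels: int = 4000

    def __post_init__(self) -> None:
        if self.mode not in ("coverage", "sparing"):
            raise InvalidArgumentError(f"unknown planning mode {self.mode!r}")
        if not 0.0 < self.target_coverage <= 1.0:
            raise InvalidArgumentError("target_coverage must lie in (0, 1]")


@dataclass
class DoseMap:
    """Per-voxel fluence (J/mm^2) with provenance."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    wavelength_nm: int
    energies_j: np.ndarray

    @property
    def dims(self):
        return self.values.shape


@dataclass
class Plan:
    """Optimized per-source energies plus achieved plan quality."""

    energies_j: np.ndarray
    coverage: float
    damage_volumes_cm3: dict
    mode: str
    wavelength_nm: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def total_energy_j(self) -> float:
        return float(np.sum(self.energies_j))


def superpose_dose(kernels: list[FluenceKernel], energies_j) -> DoseMap:
    """Voxelwise dose ``sum_j E_j * kernel_j`` (J/mm^2)."""
    if len(kernels) == 0:
        raise InvalidArgumentError("at least one kernel required")
    energies = np.asarray(energies_j, dtype=float)
    if energies.shape != (len(kernels),):
        raise InvalidArgumentError("one energy per kernel required")
    if np.any(energies < 0):
        raise InvalidArgumentError("energies must be nonnegative")
    k0 = kernels[0]
    for k in kernels[1:]:
        if k.dims != k0.dims or k.spacing != k0.spacing or k.origin != k0.origin:
            raise IncompatibleKernelsError("kernels do not share a voxel grid")
        if k.wavelength_nm != k0.wavelength_nm:
            raise IncompatibleKernelsError("kernels mix wavelengths")
    dose = np.zeros(k0.dims, dtype=np.float64)
    for e, k in zip(energies, kernels):
        if e != 0.0:
            dose += e * k.values
    return DoseMap(values=dose, spacing=k0.spacing, origin=k0.origin,
                   wavelength_nm=k0.wavelength_nm, energies_j=energies)


def _thresholds(lib_view: dict[str, TissueEntry]) -> dict[str, float]:
    try:
        return {t: lib_view[t].thresholds.phi_threshold
                for t in ("metastasis", "spinal_cord", "bone", "muscle")}
    except KeyError as e:
        raise NotFoundError(f"tissue library view lacks thresholds for {e}") from None


def _subsample(idx: np.ndarray, cap: int) -> np.ndarray:
    if len(idx) <= cap:
        return idx
    stride = int(np.ceil(len(idx) / cap))
    return idx[::stride]


def _kernel_matrix(kernels, flat_idx) -> np.ndarray:
    """(n_voxels, n_sources) matrix of kernel values at the given flat indices."""
    return np.stack([k.values.ravel()[flat_idx] for k in kernels], axis=1)


def _full_metrics(kernels, energies, vol, thr) -> tuple[float, dict]:
    dose = superpose_dose(kernels, energies).values
    vv = vol.voxel_volume_mm3
    damage = {}
    for tissue, key in (("metastasis", "metastasis"), ("spinal_cord", "spinal_cord"),
                        ("bone", "bone"), ("muscle", "muscle")):
        m = vol.mask(tissue)
        damage[tissue] = float(np.count_nonzero(dose[m] >= thr[key]) * vv / 1000.0)
    met = vol.mask("metastasis")
    n_met = int(np.count_nonzero(met))
    coverage = (float(np.count_nonzero(dose[met] >= thr["metastasis"]) / n_met)
                if n_met else 0.0)
    return coverage, damage


def _solve_penalty_lp(K_tum, phi_tum, oar_blocks, w_t, energy_scale):
    """Inner LP of coverage mode.

    Variables: [E (n_src), t (tumour underdose), o (OAR overdose), Emax].
    Minimize  w_t * sum(t)*tw + sum_oar w_oar * sum(o)*ow
              + eta1 * sum(E) + eta2 * Emax
    s.t.      K_tum E + t >= phi_tum;  K_oar E - o <= phi_oar;  E <= Emax.
    """
    n_src = K_tum.shape[1]
    n_t = K_tum.shape[0]
    n_o = sum(K.shape[0] for K, _, _, _ in oar_blocks)

    obj_scale = max(n_t * phi_tum, 1e-30)
    eta1 = 1e-6 * obj_scale / max(energy_scale, 1e-30)
    eta2 = 0.1 * eta1

    c = np.concatenate([
        np.full(n_src, eta1),
        np.full(n_t, w_t),
        np.concatenate([np.full(K.shape[0], w * sw) for K, _, w, sw in oar_blocks])
        if n_o else np.zeros(0),
        [eta2],
    ])
    # tumour rows: -K E - t <= -phi_tum
    rows = [sps.hstack([sps.csr_matrix(-K_tum), -sps.identity(n_t),
                        sps.csr_matrix((n_t, n_o)), sps.csr_matrix((n_t, 1))])]
    rhs = [np.full(n_t, -phi_tum)]
    # OAR rows: K E - o <= phi_oar
    col0 = 0
    for K, phi, _, _ in oar_blocks:
        m = K.shape[0]
        sel = sps.csr_matrix(
            (np.ones(m), (np.arange(m), col0 + np.arange(m))), shape=(m, n_o))
        rows.append(sps.hstack([sps.csr_matrix(K), sps.csr_matrix((m, n_t)),
                                -sel, sps.csr_matrix((m, 1))]))
        rhs.append(np.full(m, phi))
        col0 += m
    # peak-energy rows: E_j - Emax <= 0
    rows.append(sps.hstack([sps.identity(n_src), sps.csr_matrix((n_src, n_t + n_o)),
                            -np.ones((n_src, 1))]))
    rhs.append(np.zeros(n_src))

    res = linprog(c, A_ub=sps.vstack(rows, format="csr"),
                  b_ub=np.concatenate(rhs), bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return np.maximum(res.x[:n_src], 0.0), res


def optimize_coverage(kernels: list[FluenceKernel], vol: LabelVolume,
                      lib_view: dict[str, TissueEntry], cfg: PlanConfig) -> Plan:
    """Coverage-mode planning: reach the target tumour coverage while
    penalizing organ-at-risk overdose.

    The tumour weight is raised/lowered by monotone bisection until the
    full-grid coverage lands in ``[target, target + tol]`` (or the weight
    bounds are exhausted, in which case the plan at the bound is returned
    with ``diagnostics["coverage_reached"] = False``).
    """
    if cfg.mode != "coverage":
        raise InvalidArgumentError("cfg.mode must be 'coverage'")
    if len(kernels) == 0:
        raise InvalidArgumentError("at least one kernel required")
    thr = _thresholds(lib_view)
    lbl_flat = vol.labels.ravel()
    from .phantom import LABELS
    tum_idx = _subsample(np.flatnonzero(lbl_flat == LABELS["metastasis"]),
                         cfg.max_lp_voxels)
    if len(tum_idx) == 0:
        raise InvalidArgumentError("volume contains no tumour voxels")
    K_tum = _kernel_matrix(kernels, tum_idx)

    oar_blocks = []
    for tissue in ("spinal_cord", "bone", "muscle"):
        idx_full = np.flatnonzero(lbl_flat == LABELS[tissue])
        idx = _subsample(idx_full, cfg.max_lp_voxels)
        if len(idx) == 0:
            continue
        # subsample weight keeps the penalty an unbiased volume integral
        sw = len(idx_full) / len(idx)
        oar_blocks.append((_kernel_matrix(kernels, idx), thr[tissue],
                           cfg.oar_weights.get(tissue, 0.0), sw))

    # energy scale: what a single voxel needs from the combined kernels
    ksum = K_tum.sum(axis=1)
    e_scale = thr["metastasis"] / max(np.percentile(ksum[ksum > 0], 50), 1e-30) \
        if np.any(ksum > 0) else 1.0

    tum_sw = np.count_nonzero(lbl_flat == LABELS["metastasis"]) / len(tum_idx)

    def solve(w_t):
        energies, res = _solve_penalty_lp(K_tum, thr["metastasis"], oar_blocks,
                                          w_t * tum_sw, e_scale)
        cov, dmg = _full_metrics(kernels, energies, vol, thr)
        return energies, cov, dmg, res

    trace = []
    if cfg.tumour_weight is not None:
        energies, cov, dmg, _ = solve(cfg.tumour_weight)
        trace.append((cfg.tumour_weight, cov))
        reached = cov >= cfg.target_coverage
        return Plan(energies_j=energies, coverage=cov, damage_volumes_cm3=dmg,
                    mode="coverage", wavelength_nm=kernels[0].wavelength_nm,
                    diagnostics={"tumour_weight": cfg.tumour_weight,
                                 "coverage_reached": bool(reached),
                                 "weight_trace": trace})

    # expand upward from the minimum weight until coverage target is met
    lo, hi = cfg.tumour_weight_min, cfg.tumour_weight_min
    candidates = []  # (cord damage, total energy, plan tuple) among target-meeting
    e_lo, cov_lo, dmg_lo, _ = solve(lo)
    trace.append((lo, cov_lo))
    best_any = (lo, e_lo, cov_lo, dmg_lo)
    if cov_lo < cfg.target_coverage:
        cov_hi = cov_lo
        while hi < cfg.tumour_weight_max:
            hi = min(hi * 8.0, cfg.tumour_weight_max)
            e_hi, cov_hi, dmg_hi, _ = solve(hi)
            trace.append((hi, cov_hi))
            best_any = (hi, e_hi, cov_hi, dmg_hi)
            if cov_hi >= cfg.target_coverage:
                candidates.append((dmg_hi["spinal_cord"], float(np.sum(e_hi)),
                                   e_hi, cov_hi, dmg_hi, hi))
                break
        if cov_hi < cfg.target_coverage:
            w, e, cov, dmg = best_any
            return Plan(energies_j=e, coverage=cov, damage_volumes_cm3=dmg,
                        mode="coverage", wavelength_nm=kernels[0].wavelength_nm,
                        diagnostics={"tumour_weight": w, "coverage_reached": False,
                                     "weight_trace": trace})
    else:
        candidates.append((dmg_lo["spinal_cord"], float(np.sum(e_lo)),
                           e_lo, cov_lo, dmg_lo, lo))
        hi = lo

    # bisect into [target, target + tol]
    for _ in range(cfg.max_iterations):
        top = candidates[-1]
        if top[3] <= cfg.target_coverage + cfg.coverage_tol or hi / max(lo, 1e-300) < 1.0001:
            break
        mid = float(np.sqrt(lo * hi))  # geometric bisection on the weight
        e_m, cov_m, dmg_m, _ = solve(mid)
        trace.append((mid, cov_m))
        if cov_m >= cfg.target_coverage:
            candidates.append((dmg_m["spinal_cord"], float(np.sum(e_m)),
                               e_m, cov_m, dmg_m, mid))
            hi = mid
        else:
            lo = mid

    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, energies, cov, dmg, w = candidates[0]
    # trim: scale all energies down until coverage just meets the target
    # band (dose is linear in energy, so coverage is monotone in the scale)
    if cov > cfg.target_coverage + cfg.coverage_tol:
        a_lo, a_hi = 0.0, 1.0
        for _ in range(40):
            a_mid = 0.5 * (a_lo + a_hi)
            cov_m, _ = _full_metrics(kernels, a_mid * energies, vol, thr)
            if cov_m >= cfg.target_coverage:
                a_hi = a_mid
                if cov_m <= cfg.target_coverage + cfg.coverage_tol:
                    break
            else:
                a_lo = a_mid
        energies = a_hi * energies
        cov, dmg = _full_metrics(kernels, energies, vol, thr)
    return Plan(energies_j=energies, coverage=cov, damage_volumes_cm3=dmg,
                mode="coverage", wavelength_nm=kernels[0].wavelength_nm,
                diagnostics={"tumour_weight": w, "coverage_reached": True,
                             "weight_trace": trace})


def optimize_sparing(kernels: list[FluenceKernel], vol: LabelVolume,
                     lib_view: dict[str, TissueEntry], cfg: PlanConfig) -> Plan:
    """Sparing-mode planning: maximize tumour coverage with zero cord necrosis.

    Hard per-voxel constraints hold every spinal-cord voxel strictly below
    its threshold fluence (a relative numerical margin of 1e-6 keeps boundary
    voxels out of the damaged set); the objective maximizes the concave
    surrogate ``sum_i min(d_i, phi_tumour)`` over a tumour voxel subsample.
    ``E = 0`` is always feasible, so the solve cannot fail.
    """
    if cfg.mode != "sparing":
        raise InvalidArgumentError("cfg.mode must be 'sparing'")
    if len(kernels) == 0:
        raise InvalidArgumentError("at least one kernel required")
    thr = _thresholds(lib_view)
    from .phantom import LABELS
    lbl_flat = vol.labels.ravel()
    tum_idx = _subsample(np.flatnonzero(lbl_flat == LABELS["metastasis"]),
                         cfg.max_lp_voxels)
    cord_idx = np.flatnonzero(lbl_flat == LABELS["spinal_cord"])  # full grid
    if len(tum_idx) == 0:
        raise InvalidArgumentError("volume contains no tumour voxels")
    K_tum = _kernel_matrix(kernels, tum_idx)
    n_src, n_t = K_tum.shape[1], K_tum.shape[0]
    phi_tum = thr["metastasis"]

    ksum = K_tum.sum(axis=1)
    e_scale = phi_tum / max(np.percentile(ksum[ksum > 0], 50), 1e-30) \
        if np.any(ksum > 0) else 1.0
    obj_scale = n_t * phi_tum
    eta1 = 1e-6 * obj_scale / max(e_scale, 1e-30)
    eta2 = 0.1 * eta1

    # variables: [E, z, Emax]; maximize sum z  ->  minimize -sum z + ties
    c = np.concatenate([np.full(n_src, eta1), -np.ones(n_t), [eta2]])
    rows = [
        # z - K E <= 0
        sps.hstack([sps.csr_matrix(-K_tum), sps.identity(n_t),
                    sps.csr_matrix((n_t, 1))]),
        # E_j - Emax <= 0
        sps.hstack([sps.identity(n_src), sps.csr_matrix((n_src, n_t)),
                    -np.ones((n_src, 1))]),
    ]
    rhs = [np.zeros(n_t), np.zeros(n_src)]
    soft_pen = None
    if len(cord_idx):
        K_cord = _kernel_matrix(kernels, cord_idx)
        if cfg.cord_constraint == "hard":
            rows.append(sps.hstack([sps.csr_matrix(K_cord),
                                    sps.csr_matrix((K_cord.shape[0], n_t + 1))]))
            rhs.append(np.full(K_cord.shape[0],
                               thr["spinal_cord"] * (1.0 - 1e-6)))
        else:
            # soft: penalized overdose slack o >= K_cord E - phi_cord
            m = K_cord.shape[0]
            for i, r in enumerate(rows):
                rows[i] = sps.hstack([r, sps.csr_matrix((r.shape[0], m))])
            c = np.concatenate([c, np.full(m, cfg.soft_cord_weight)])
            rows.append(sps.hstack([sps.csr_matrix(K_cord),
                                    sps.csr_matrix((m, n_t + 1)),
                                    -sps.identity(m)]))
            rhs.append(np.full(m, thr["spinal_cord"]))
            soft_pen = m
    bounds = [(0, None)] * n_src + [(0, phi_tum)] * n_t + [(0, None)]
    if soft_pen:
        bounds += [(0, None)] * soft_pen
    res = linprog(c, A_ub=sps.vstack(rows, format="csr"), b_ub=np.concatenate(rhs),
                  bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    energies = np.maximum(res.x[:n_src], 0.0)
    cov, dmg = _full_metrics(kernels, energies, vol, thr)
    return Plan(energies_j=energies, coverage=cov, damage_volumes_cm3=dmg,
                mode="sparing", wavelength_nm=kernels[0].wavelength_nm,
                diagnostics={"cord_constraint": cfg.cord_constraint,
                             "lp_status": res.status})
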