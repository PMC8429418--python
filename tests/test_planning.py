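"""Dose superposition and LP-based power allocation."""

import numpy as np
import pytest

import spinepdt as sp
from spinepdt.errors import IncompatibleKernelsError, InvalidArgumentError
from spinepdt.planning import PlanConfig, optimize_coverage, optimize_sparing
from spinepdt.transport import FluenceKernel, RNGSpec

from conftest import make_synthetic_kernel


def _kernel_from_array(values, wavelength_nm=690, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return FluenceKernel(values=np.asarray(values, float), rel_error=None,
                         spacing=spacing, origin=origin, n_packets=0,
                         rng=RNGSpec(0), source=None, wavelength_nm=wavelength_nm)


class TestSuperposeDose:
    def test_zero_energies_zero_dose(self, toy_kernels):
        dose = sp.superpose_dose(toy_kernels, [0.0, 0.0])
        assert np.all(dose.values == 0.0)

    def test_homogeneity(self, toy_kernels):
        d1 = sp.superpose_dose(toy_kernels, [2.0, 3.0])
        d2 = sp.superpose_dose(toy_kernels, [4.0, 6.0])
        assert np.allclose(d2.values, 2.0 * d1.values)

    def test_loop_oracle_on_small_grid(self):
        rng = np.random.default_rng(0)
        kernels = [_kernel_from_array(rng.random((5, 5, 5))) for _ in range(3)]
        energies = [1.5, 0.0, 2.25]
        dose = sp.superpose_dose(kernels, energies)
        expected = np.zeros((5, 5, 5))
        for i in np.ndindex(5, 5, 5):
            for e, k in zip(energies, kernels):
                expected[i] += e * k.values[i]
        assert np.allclose(dose.values, expected)

    def test_grid_mismatch_rejected(self, toy_kernels):
        other = _kernel_from_array(np.zeros((2, 2, 2)))
        with pytest.raises(IncompatibleKernelsError):
            sp.superpose_dose([toy_kernels[0], other], [1.0, 1.0])

    def test_wavelength_mismatch_rejected(self, toy_kernels):
        other = _kernel_from_array(toy_kernels[0].values, wavelength_nm=565)
        with pytest.raises(IncompatibleKernelsError):
            sp.superpose_dose([toy_kernels[0], other], [1.0, 1.0])

    def test_negative_energy_rejected(self, toy_kernels):
        with pytest.raises(InvalidArgumentError):
            sp.superpose_dose(toy_kernels, [1.0, -1.0])


def brute_force_penalty_objective(K_tum, phi_tum, K_oar, phi_oar, w_oar, w_t,
                                  energies):
    """Independent evaluation of the coverage-mode penalty objective."""
    d_tum = K_tum @ energies
    d_oar = K_oar @ energies
    return (w_t * np.sum(np.maximum(phi_tum - d_tum, 0.0))
            + w_oar * np.sum(np.maximum(d_oar - phi_oar, 0.0)))


class TestCoverageMode:
    def test_toy_lp_matches_exhaustive_search(self):
        """3-voxel / 2-kernel problem: the LP optimum matches a dense grid
        search over the energy plane to 1e-3."""
        labels = np.array([[[3, 3, 4]]], dtype=np.uint8)  # 2 tumour + 1 cord
        vol = sp.LabelVolume(labels=labels, spacing=(1, 1, 1))
        lib = sp.tissue_library(690)
        K = np.array([[0.010, 0.002],
                      [0.004, 0.012],
                      [0.003, 0.003]])  # rows: voxels, cols: sources
        kernels = [_kernel_from_array(K[:, j].reshape(1, 1, 3)) for j in range(2)]
        w_t = 2.0
        cfg = PlanConfig(mode="coverage", tumour_weight=w_t)
        plan = optimize_coverage(kernels, vol, lib, cfg)

        phi_tum, phi_cord = 0.4, 0.02
        obj_lp = brute_force_penalty_objective(
            K[:2], phi_tum, K[2:], phi_cord, 1.0, w_t, plan.energies_j)
        # exhaustive grid over the energy plane, with two refinement stages
        lo = np.array([0.0, 0.0])
        width = 200.0
        best, best_e = np.inf, lo
        for _ in range(3):
            g1 = np.linspace(lo[0], lo[0] + width, 81)
            g2 = np.linspace(lo[1], lo[1] + width, 81)
            for e1 in g1:
                for e2 in g2:
                    obj = brute_force_penalty_objective(
                        K[:2], phi_tum, K[2:], phi_cord, 1.0, w_t,
                        np.array([e1, e2]))
                    if obj < best:
                        best, best_e = obj, np.array([e1, e2])
            step = width / 80
            lo = np.maximum(best_e - 2 * step, 0.0)
            width = 4 * step
        assert abs(obj_lp - best) <= 1e-3

    def test_single_source_closed_form_energy(self):
        """Tumour-only anatomy, one kernel: the optimal energy is the
        threshold divided by the coverage-defining quantile kernel value."""
        n = 100
        labels = np.full((n, 1, 1), sp.LABELS["metastasis"], np.uint8)
        vol = sp.LabelVolume(labels=labels, spacing=(1, 1, 1))
        lib = sp.tissue_library(690)
        rng = np.random.default_rng(12)
        k = np.sort(rng.random(n) + 0.01)[::-1].reshape(n, 1, 1) * 1e-3
        kernels = [_kernel_from_array(k)]
        cfg = PlanConfig(mode="coverage", target_coverage=0.9, coverage_tol=0.002)
        plan = optimize_coverage(kernels, vol, lib, cfg)
        phi_tum = 0.4
        k_sorted = np.sort(k.ravel())[::-1]
        # covering exactly 90 of 100 voxels requires E in [phi/k_(90), phi/k_(91))
        e_low = phi_tum / k_sorted[89]
        e_high = phi_tum / k_sorted[90]
        assert plan.coverage == pytest.approx(0.9, abs=1e-12)
        assert e_low * (1 - 1e-9) <= plan.total_energy_j < e_high

    def test_symmetric_phantom_symmetric_energies(self, toy_vol, toy_kernels):
        cfg = PlanConfig(mode="coverage", target_coverage=0.9)
        plan = optimize_coverage(toy_kernels, toy_vol, sp.tissue_library(690), cfg)
        assert plan.diagnostics["coverage_reached"]
        assert abs(plan.energies_j[0] - plan.energies_j[1]) \
            <= 0.02 * plan.total_energy_j

    def test_coverage_monotone_in_tumour_weight(self, toy_vol, toy_kernels):
        lib = sp.tissue_library(690)
        covs = []
        for w in (1e-3, 1e-1, 10.0, 1e3):
            plan = optimize_coverage(toy_kernels, toy_vol, lib,
                                     PlanConfig(mode="coverage", tumour_weight=w))
            covs.append(plan.coverage)
        assert all(b >= a - 1e-9 for a, b in zip(covs, covs[1:]))

    def test_plan_dose_round_trip(self, toy_vol, toy_kernels):
        lib = sp.tissue_library(690)
        plan = optimize_coverage(toy_kernels, toy_vol, lib,
                                 PlanConfig(mode="coverage"))
        dose = sp.superpose_dose(toy_kernels, plan.energies_j)
        met = toy_vol.mask("metastasis")
        phi = lib["metastasis"].thresholds.phi_threshold
        cov = np.count_nonzero(dose.values[met] >= phi) / np.count_nonzero(met)
        assert cov == pytest.approx(plan.coverage, abs=1e-12)

    def test_unreachable_target_flagged(self, toy_vol):
        # half the tumour is optically shielded (zero kernel), so 90%
        # coverage is unattainable at any energy or tumour weight
        values = np.full(toy_vol.dims, 1e-4)
        met = toy_vol.mask("metastasis")
        xs = np.where(met.any(axis=(1, 2)))[0]
        values[xs[len(xs) // 2]:, :, :][met[xs[len(xs) // 2]:, :, :]] = 0.0
        shielded = _kernel_from_array(values)
        cfg = PlanConfig(mode="coverage", target_coverage=0.9,
                         tumour_weight_max=100.0)
        plan = optimize_coverage([shielded], toy_vol, sp.tissue_library(690), cfg)
        assert not plan.diagnostics["coverage_reached"]
        assert plan.coverage < 0.9


class TestSparingMode:
    def test_cord_damage_zero_by_construction(self, toy_vol, toy_kernels):
        lib = sp.tissue_library(690)
        plan = optimize_sparing(toy_kernels, toy_vol, lib, PlanConfig(mode="sparing"))
        dose = sp.superpose_dose(toy_kernels, plan.energies_j)
        phi_cord = lib["spinal_cord"].thresholds.phi_threshold
        cord = toy_vol.mask("spinal_cord")
        assert np.count_nonzero(dose.values[cord] >= phi_cord) == 0
        assert plan.damage_volumes_cm3["spinal_cord"] == 0.0

    def test_infinite_cord_threshold_is_unconstrained(self, toy_vol, toy_kernels):
        lib = dict(sp.tissue_library(690))
        relaxed = dict(lib)
        relaxed["spinal_cord"] = sp.TissueEntry(
            optics=lib["spinal_cord"].optics,
            thresholds=sp.ThresholdParams(
                T=lib["spinal_cord"].thresholds.T,
                uptake_C=lib["spinal_cord"].thresholds.uptake_C,
                eps_molar=lib["spinal_cord"].thresholds.eps_molar,
                phi_threshold=1e9))
        plan_relaxed = optimize_sparing(toy_kernels, toy_vol, relaxed,
                                        PlanConfig(mode="sparing"))
        # with an unreachable cord threshold the constraint is inactive and
        # coverage is maximal (every tumour voxel reachable gets covered)
        assert plan_relaxed.coverage == pytest.approx(1.0, abs=1e-9)

    def test_sparing_never_beats_coverage_mode(self, toy_vol, toy_kernels):
        lib = sp.tissue_library(690)
        sparing = optimize_sparing(toy_kernels, toy_vol, lib,
                                   PlanConfig(mode="sparing"))
        coverage = optimize_coverage(toy_kernels, toy_vol, lib,
                                     PlanConfig(mode="coverage"))
        assert sparing.coverage <= coverage.coverage + 1e-9

    def test_soft_variant_runs(self, toy_vol, toy_kernels):
        lib = sp.tissue_library(690)
        plan = optimize_sparing(toy_kernels, toy_vol, lib,
                                PlanConfig(mode="sparing", cord_constraint="soft"))
        assert plan.total_energy_j >= 0.0


class TestPlanConfig:
    def test_invalid_mode_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PlanConfig(mode="ablate")

    def test_invalid_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PlanConfig(target_coverage=1.5)
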