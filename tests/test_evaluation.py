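"""DVHs, damage reports, energy bookkeeping and dose export."""

import numpy as np
import pytest

import spinepdt as sp
from spinepdt.errors import InvalidArgumentError, NotFoundError
from spinepdt.planning import DoseMap


def _dose_from_array(values, vol, wavelength_nm=690, energies=(1.0,)):
    return DoseMap(values=np.asarray(values, float), spacing=vol.spacing,
                   origin=vol.origin, wavelength_nm=wavelength_nm,
                   energies_j=np.asarray(energies, float))


class TestDVH:
    def test_uniform_dose_is_step_function(self, toy_vol):
        d = np.zeros(toy_vol.dims)
        d[toy_vol.mask("metastasis")] = 0.5
        dvh = sp.compute_dvh(_dose_from_array(d, toy_vol), toy_vol, "metastasis")
        assert dvh.volume_fraction[0] == 1.0
        assert np.all(dvh.volume_fraction[dvh.dose_j_per_mm2 <= 0.5] == 1.0)
        assert np.all(dvh.volume_fraction[dvh.dose_j_per_mm2 > 0.5] == 0.0)

    def test_starts_at_one_ends_at_zero(self, toy_vol):
        rng = np.random.default_rng(5)
        d = rng.random(toy_vol.dims)
        dvh = sp.compute_dvh(_dose_from_array(d, toy_vol), toy_vol, "bone")
        assert dvh.volume_fraction[0] == 1.0
        assert dvh.volume_fraction[-1] == 0.0

    def test_monotone_nonincreasing(self, toy_vol):
        rng = np.random.default_rng(6)
        d = rng.random(toy_vol.dims) ** 3
        for tissue in ("metastasis", "spinal_cord", "bone", "muscle"):
            dvh = sp.compute_dvh(_dose_from_array(d, toy_vol), toy_vol, tissue)
            assert np.all(np.diff(dvh.volume_fraction) <= 1e-15)

    def test_matches_damage_fraction_at_threshold(self, toy_vol):
        """The DVH evaluated at the threshold fluence reproduces the damage
        fraction reported by the threshold model."""
        rng = np.random.default_rng(8)
        d = rng.random(toy_vol.dims) * 0.05
        dose = _dose_from_array(d, toy_vol)
        lib = sp.tissue_library(690)
        report = sp.damage_report(dose, toy_vol, lib)
        phi = lib["spinal_cord"].thresholds.phi_threshold
        cord_doses = np.sort(d[toy_vol.mask("spinal_cord")])
        exact = 1.0 - np.searchsorted(cord_doses, phi, side="left") / len(cord_doses)
        assert exact * 100 == pytest.approx(report.damage_fractions_pct["spinal_cord"])
        dvh = sp.compute_dvh(dose, toy_vol, "spinal_cord", n_bins=2048)
        assert dvh.at(phi) == pytest.approx(exact, abs=2.0 / 2048)

    def test_absent_tissue_rejected(self, homogeneous_muscle_vol):
        d = np.zeros(homogeneous_muscle_vol.dims)
        with pytest.raises(NotFoundError):
            sp.compute_dvh(_dose_from_array(d, homogeneous_muscle_vol),
                           homogeneous_muscle_vol, "metastasis")

    def test_csv_export(self, toy_vol, tmp_path):
        d = np.zeros(toy_vol.dims)
        d[toy_vol.mask("bone")] = 0.1
        dvh = sp.compute_dvh(_dose_from_array(d, toy_vol), toy_vol, "bone")
        dvh.to_csv(tmp_path / "dvh.csv")
        import pandas as pd
        back = pd.read_csv(tmp_path / "dvh.csv")
        assert np.allclose(back["volume_fraction"], dvh.volume_fraction)


class TestDamageReport:
    def test_below_threshold_no_damage(self, toy_vol):
        d = np.full(toy_vol.dims, 1e-6)
        report = sp.damage_report(_dose_from_array(d, toy_vol), toy_vol,
                                  sp.tissue_library(690))
        assert all(v == 0.0 for v in report.damaged_volumes_cm3.values())

    def test_loop_oracle(self):
        labels = np.zeros((5, 5, 5), np.uint8)
        labels[:2] = sp.LABELS["metastasis"]
        labels[2:4] = sp.LABELS["spinal_cord"]
        labels[4:] = sp.LABELS["muscle"]
        vol = sp.LabelVolume(labels=labels, spacing=(2, 2, 2))
        rng = np.random.default_rng(9)
        d = rng.random((5, 5, 5))
        lib = sp.tissue_library(690)
        report = sp.damage_report(_dose_from_array(d, vol), vol, lib)
        # independent per-voxel tally
        expected = {"metastasis": 0, "spinal_cord": 0, "muscle": 0}
        thr = {"metastasis": 0.4, "spinal_cord": 0.02, "muscle": 0.1}
        names = {3: "metastasis", 4: "spinal_cord", 1: "muscle"}
        for idx in np.ndindex(5, 5, 5):
            name = names[int(labels[idx])]
            if d[idx] >= thr[name]:
                expected[name] += 1
        for name, count in expected.items():
            assert report.damaged_volumes_cm3[name] == pytest.approx(count * 8 / 1000.0)

    def test_volume_conservation(self, toy_vol):
        rng = np.random.default_rng(10)
        d = rng.random(toy_vol.dims)
        report = sp.damage_report(_dose_from_array(d, toy_vol), toy_vol,
                                  sp.tissue_library(690))
        for tissue, total in report.tissue_volumes_cm3.items():
            assert 0.0 <= report.damaged_volumes_cm3[tissue] <= total + 1e-12

    def test_json_round_trip(self, toy_vol, tmp_path):
        import json
        d = np.zeros(toy_vol.dims)
        report = sp.damage_report(_dose_from_array(d, toy_vol), toy_vol,
                                  sp.tissue_library(690))
        report.to_json(tmp_path / "report.json")
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["wavelength_nm"] == 690


class TestEnergyBookkeeping:
    """The published per-source energies and cross-wavelength ratio."""

    def _report(self, energies, wavelength_nm):
        return sp.DamageReport(
            wavelength_nm=wavelength_nm, mode="coverage",
            tissue_volumes_cm3={}, damaged_volumes_cm3={},
            damage_fractions_pct={}, tumour_coverage_pct=90.0,
            energies_j=list(energies), total_energy_j=float(np.sum(energies)))

    def test_cut_end_energies_sum_to_total(self):
        r690 = self._report([439.6, 487.6, 189.6, 130.8], 690)
        assert r690.total_energy_j == pytest.approx(1247.6, abs=1e-9)

    def test_cross_wavelength_ratio(self):
        r690 = self._report([439.6, 487.6, 189.6, 130.8], 690)
        r565 = self._report([64.6e3, 49.5e3, 32.4e3, 20.8e3], 565)
        assert round(sp.energy_ratio(r565, r690)) == 134

    def test_ratio_identity_and_reciprocity(self):
        a = self._report([10.0], 690)
        b = self._report([2.5], 690)
        assert sp.energy_ratio(a, a) == 1.0
        assert sp.energy_ratio(a, b) * sp.energy_ratio(b, a) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        a = self._report([1.0], 690)
        z = self._report([0.0], 690)
        with pytest.raises(InvalidArgumentError):
            sp.energy_ratio(a, z)


class TestTreatmentTime:
    def test_diffuser_delivery_time(self):
        # 2914 J at 200 mW/cm over 6 cm of emitting length -> ~40.5 min
        t = sp.treatment_time(2914.0, 0.2, 6.0)
        assert t == pytest.approx(2428.33, abs=0.01)
        assert t / 60 == pytest.approx(40.5, abs=0.1)

    def test_power_inverse_proportionality(self):
        assert sp.treatment_time(100.0, 0.4, 5.0) \
            == pytest.approx(sp.treatment_time(100.0, 0.2, 5.0) / 2)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sp.treatment_time(100.0, 0.2, 0.0)
        with pytest.raises(InvalidArgumentError):
            sp.treatment_time(100.0, -0.2, 5.0)


class TestDoseExport:
    def test_round_trip(self, toy_vol, tmp_path):
        rng = np.random.default_rng(11)
        d = rng.random(toy_vol.dims).astype(np.float32).astype(float)
        dose = _dose_from_array(d, toy_vol)
        sp.export_dose_volume(dose, tmp_path / "dose.nii.gz")
        back = sp.read_dose_volume(tmp_path / "dose.nii.gz")
        assert np.allclose(back.values, d, rtol=1e-6)

    def test_zero_threshold_mask_is_support(self, toy_vol):
        d = np.zeros(toy_vol.dims)
        d[toy_vol.mask("metastasis")] = 0.3
        dose = _dose_from_array(d, toy_vol)
        assert np.array_equal(sp.threshold_mask(dose, 0.0), d > 0)

    def test_mask_consistent_with_damage_report(self, toy_vol):
        rng = np.random.default_rng(12)
        d = rng.random(toy_vol.dims)
        dose = _dose_from_array(d, toy_vol)
        lib = sp.tissue_library(690)
        report = sp.damage_report(dose, toy_vol, lib)
        phi = lib["metastasis"].thresholds.phi_threshold
        mask = sp.threshold_mask(dose, phi) & toy_vol.mask("metastasis")
        vv = toy_vol.voxel_volume_mm3
        assert mask.sum() * vv / 1000.0 == pytest.approx(
            report.damaged_volumes_cm3["metastasis"])


class TestReportTable:
    def test_columns_and_rows(self, toy_vol):
        d = np.zeros(toy_vol.dims)
        lib = sp.tissue_library(690)
        reports = [sp.damage_report(_dose_from_array(d, toy_vol), toy_vol, lib)
                   for _ in range(2)]
        table = sp.reports_to_table(reports, labels=["a", "b"])
        assert list(table["run"]) == ["a", "b"]
        assert "cord_damage_cm3" in table.columns
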