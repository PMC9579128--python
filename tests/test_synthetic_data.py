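"""Calibrated synthetic spectra: targets, determinism, provenance."""
from importlib.resources import files

import numpy as np
import pytest

from gdnano.physics_tables import InvalidInputError
from gdnano.dose_damage import enhancement_percent, total_dose, total_strand_breaks
from gdnano.synthetic_data import (
    calibrate,
    default_yield_table,
    expected_alpha_spectrum,
    generate_alpha_spectra,
    generate_neutron_fluxes,
    load_printed_tables,
    load_recipe,
    save_calibration,
)


@pytest.fixture(scope="module")
def calibration():
    return calibrate()


@pytest.fixture(scope="module")
def recipe():
    return load_recipe()


class TestCalibration:
    def test_all_targets_within_tolerance(self, calibration):
        assert calibration.worst_residual() <= 0.02

    def test_no_agent_dose_solved_exactly(self, calibration, let_table):
        spec = expected_alpha_spectrum(calibration.recipe, "none")
        dose = total_dose(spec, let_table).total_dose
        assert dose == pytest.approx(7e-9, rel=1e-12)

    def test_full_calibration_gives_100_percent_gdf4_dose_enhancement(
            self, calibration, let_table):
        d0 = total_dose(expected_alpha_spectrum(calibration.recipe, "none"),
                        let_table).total_dose
        d1 = total_dose(expected_alpha_spectrum(calibration.recipe, "GdF4"),
                        let_table).total_dose
        assert enhancement_percent(d1, d0, rounding="int") == 100.0

    def test_scale_doubling_preserves_enhancements(self, calibration, let_table):
        import copy
        rec = copy.deepcopy(calibration.recipe)
        base = {}
        for agent in ("none", "C"):
            base[agent] = total_dose(expected_alpha_spectrum(rec, agent),
                                     let_table).total_dose
        rec.baseline["scale"] *= 2.0
        for p in rec.excess.values():
            p["scale"] *= 2.0
        doubled = {}
        for agent in ("none", "C"):
            doubled[agent] = total_dose(expected_alpha_spectrum(rec, agent),
                                        let_table).total_dose
        assert enhancement_percent(doubled["C"], doubled["none"], "raw") == \
            pytest.approx(enhancement_percent(base["C"], base["none"], "raw"),
                          rel=1e-12)

    def test_recalibration_is_idempotent(self, recipe):
        import copy
        before = copy.deepcopy(recipe)
        res = calibrate(recipe=recipe)
        assert res.recipe.baseline["scale"] == pytest.approx(
            before.baseline["scale"], rel=1e-12)
        for agent in ("C", "GdF4"):
            for key in ("peak", "skew", "scale"):
                assert res.recipe.excess[agent][key] == pytest.approx(
                    before.excess[agent][key], rel=1e-12)

    def test_excess_concentrated_in_band(self, recipe):
        for agent in ("C", "GdF4"):
            spec = expected_alpha_spectrum(recipe, agent)
            base = expected_alpha_spectrum(recipe, "none")
            excess = spec.fluence - base.fluence
            assert excess[1:6].sum() / excess.sum() > 0.5


class TestShippedFixtures:
    def test_fixtures_regenerate_bit_identically(self, calibration, tmp_path):
        save_calibration(calibration, tmp_path / "calibration.yaml",
                         tmp_path / "damage_yield.tsv")
        data = files("gdnano.data")
        for name in ("calibration.yaml", "damage_yield.tsv"):
            assert (tmp_path / name).read_text() == \
                data.joinpath(name).read_text(), f"{name} is stale"

    def test_shipped_yield_table_argmax_positions(self):
        table = default_yield_table()
        assert table.energies[np.argmax(table.ssb_per_alpha)] == 2.0
        assert table.energies[np.argmax(table.dsb_per_alpha)] == 1.0


class TestGeneration:
    def test_same_seed_reproduces_spectrum(self, recipe):
        a = generate_alpha_spectra(recipe, "C", seed=1)
        b = generate_alpha_spectra(recipe, "C", seed=1)
        np.testing.assert_array_equal(a.fluence, b.fluence)

    def test_unknown_agent_rejected(self, recipe):
        with pytest.raises(InvalidInputError):
            generate_alpha_spectra(recipe, "B11")

    def test_poisson_noise_shrinks_with_event_count(self, recipe):
        expected = expected_alpha_spectrum(recipe, "none").fluence
        devs = {}
        for n in (10_000, 1_000_000):
            spec = generate_alpha_spectra(recipe, "none", seed=2, n_protons=n)
            devs[n] = np.abs(spec.fluence - expected).sum() / expected.sum()
        # relative counting error scales ~ 1/sqrt(n): two decades apart
        assert devs[1_000_000] < devs[10_000] / 3.0


class TestNeutronFluxes:
    def test_baseline_anchored_to_published_fluences(self):
        _, base = generate_neutron_fluxes(seed=3, gd_ppm=3000.0)
        anchors = load_printed_tables()["neutron_fluence_per_proton"]
        assert base.thermal_to_1kev("tumor") == pytest.approx(
            anchors["tumor"]["without_gd"], rel=1e-9)
        assert base.thermal_to_1kev("healthy") == pytest.approx(
            anchors["healthy"]["without_gd"], rel=1e-9)

    def test_zero_ppm_identity(self):
        w, wo = generate_neutron_fluxes(seed=3, gd_ppm=0.0)
        np.testing.assert_allclose(w.flux, wo.flux, rtol=1e-12)

    def test_gd_reduces_tumor_more_than_healthy(self):
        w, wo = generate_neutron_fluxes(seed=3, gd_ppm=3000.0)
        from gdnano.neutron_model import reduction_report
        rep = reduction_report(w, wo)
        assert rep["tumor"]["factor"] > rep["healthy"]["factor"] > 1.0
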