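"""Dose/strand-break integration and enhancement arithmetic."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdnano.physics_tables import InvalidInputError, let_of_energy
from gdnano.spectrum import EnergySpectrum
from gdnano.dose_damage import (
    DOSE_CONVERSION,
    DamageYieldTable,
    damage_yield,
    enhancement_percent,
    total_dose,
    total_strand_breaks,
)


def make_spectrum(fluence):
    fluence = np.asarray(fluence, float)
    return EnergySpectrum(np.linspace(0.5, 0.5 + len(fluence), len(fluence) + 1),
                          fluence)


@pytest.fixture(scope="module")
def yield_table():
    return DamageYieldTable.from_shape(100.0, 60.0)


fluence_arrays = st.lists(st.floats(0, 1e4), min_size=3, max_size=12).map(np.array)


class TestTotalDose:
    def test_zero_spectrum_gives_zero(self, let_table):
        assert total_dose(make_spectrum(np.zeros(5)), let_table).total_dose == 0.0

    def test_single_bin_hand_arithmetic(self, let_table):
        # one alpha per proton at 1 MeV: 200 keV/um * 1.6e-13
        spec = EnergySpectrum(np.array([0.5, 1.5]), np.array([1.0]))
        assert total_dose(spec, let_table).total_dose == pytest.approx(3.2e-11)

    @settings(deadline=None, max_examples=40)
    @given(fluence=fluence_arrays)
    def test_matches_elementwise_loop_oracle(self, fluence, let_table):
        spec = make_spectrum(fluence)
        got = total_dose(spec, let_table).total_dose
        oracle = 0.0
        for lo, hi, f in zip(spec.bin_edges[:-1], spec.bin_edges[1:], fluence):
            if f > 0:
                e = 0.5 * (lo + hi)
                oracle += f * let_of_energy(e, let_table) * 1.6e-13
        assert got == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    @settings(deadline=None, max_examples=30)
    @given(fluence=fluence_arrays, a=st.floats(0, 100))
    def test_linearity_and_additivity(self, fluence, a, let_table):
        spec = make_spectrum(fluence)
        d = total_dose(spec, let_table).total_dose
        assert total_dose(spec.scaled(a), let_table).total_dose == pytest.approx(
            a * d, rel=1e-12, abs=1e-300)
        assert total_dose(spec + spec, let_table).total_dose == pytest.approx(
            2 * d, rel=1e-12, abs=1e-300)

    def test_per_bin_sums_to_total(self, let_table):
        spec = make_spectrum([1.0, 2.0, 0.0, 4.0])
        res = total_dose(spec, let_table)
        assert res.per_bin.sum() == pytest.approx(res.total_dose, rel=1e-14)


class TestDamageYield:
    def test_ssb_peaks_at_2_mev(self, yield_table):
        grid = yield_table.energies
        s2, _ = damage_yield(2.0, yield_table)
        for e in grid:
            s, _ = damage_yield(float(e), yield_table)
            assert s2 >= s

    def test_dsb_peaks_at_1_mev(self, yield_table):
        _, d1 = damage_yield(1.0, yield_table)
        for e in yield_table.energies:
            _, d = damage_yield(float(e), yield_table)
            assert d1 >= d

    def test_yields_nonnegative_everywhere(self, yield_table):
        for e in np.linspace(0.3, 20.0, 40):
            s, d = damage_yield(float(e), yield_table)
            assert s >= 0 and d >= 0

    def test_wrong_argmax_rejected(self):
        with pytest.raises(InvalidInputError):
            DamageYieldTable(np.arange(1.0, 13.0), np.arange(12.0),
                             np.ones(12))


class TestTotalStrandBreaks:
    def test_zero_spectrum(self, yield_table):
        res = total_strand_breaks(make_spectrum(np.zeros(4)), yield_table)
        assert res.ssb_total == 0.0 and res.dsb_total == 0.0

    def test_single_bin_is_product(self, yield_table):
        spec = EnergySpectrum(np.array([1.5, 2.5]), np.array([3.0]))
        s, d = damage_yield(2.0, yield_table)
        res = total_strand_breaks(spec, yield_table)
        assert res.ssb_total == pytest.approx(3.0 * s, rel=1e-12)
        assert res.dsb_total == pytest.approx(3.0 * d, rel=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(fluence=fluence_arrays)
    def test_matches_loop_oracle(self, fluence, yield_table):
        spec = make_spectrum(fluence)
        res = total_strand_breaks(spec, yield_table)
        ssb = dsb = 0.0
        for lo, hi, f in zip(spec.bin_edges[:-1], spec.bin_edges[1:], fluence):
            if f > 0:
                s, d = damage_yield(0.5 * (lo + hi), yield_table)
                ssb += f * s
                dsb += f * d
        assert res.ssb_total == pytest.approx(ssb, rel=1e-12, abs=1e-300)
        assert res.dsb_total == pytest.approx(dsb, rel=1e-12, abs=1e-300)


class TestEnhancement:
    def test_doubling_is_100_percent(self):
        assert enhancement_percent(1.4e-8, 7e-9) == 100.0

    def test_published_ssb_ratio_rounds_to_124(self):
        raw = enhancement_percent(4.7e4, 2.1e4, rounding="raw")
        assert raw == pytest.approx(123.8095, abs=1e-3)
        assert enhancement_percent(4.7e4, 2.1e4, rounding="int") == 124.0

    def test_nearest_ten_policy(self):
        assert enhancement_percent(1.92e4, 8.8e3, rounding="10") == 120.0

    def test_two_significant_figures(self):
        assert enhancement_percent(4.7e4, 2.1e4, rounding="2sf") == 120.0

    def test_identity_is_zero(self):
        assert enhancement_percent(3.3, 3.3) == 0.0

    def test_invalid_baseline_rejected(self):
        with pytest.raises(InvalidInputError):
            enhancement_percent(1.0, 0.0)

    def test_scale_invariance(self):
        a, b = 1.7e4, 8.8e3
        for k in (1e-6, 1.0, 1e9):
            assert enhancement_percent(k * a, k * b, rounding="raw") == pytest.approx(
                enhancement_percent(a, b, rounding="raw"), rel=1e-12)
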