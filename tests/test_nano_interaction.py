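"""Thin-target probabilities, reaction kinematics and alpha spectra."""
import numpy as np
import pytest

from gdnano.physics_tables import (
    InvalidInputError,
    MATERIALS,
    MEV_PER_U,
    PARTICLE_MASS_U,
)
from gdnano.nano_interaction import (
    NanoTargetGeometry,
    alpha_spectrum_pair,
    expected_alpha_yield,
    interaction_probability,
    phase_space_mean_alpha_energy,
    sample_alpha_event,
    sample_product_energies,
    two_body_product_energies,
    _target_channels,
)


@pytest.fixture
def carbon_geom():
    return NanoTargetGeometry(MATERIALS["carbon"])


@pytest.fixture
def gdf4_geom():
    return NanoTargetGeometry(MATERIALS["gdf4"])


class TestInteractionProbability:
    def test_carbon_50nm_hand_value(self, channels, carbon_geom):
        # 1.103e23 cm^-3 * 0.4 b * 50 nm
        p = interaction_probability(channels["c12_p_3alpha"], carbon_geom, 20.0)
        assert p == pytest.approx(1.103e23 * 0.4e-24 * 50e-7, rel=1e-3)
        assert p == pytest.approx(2.2e-7, rel=0.01)

    def test_zero_thickness_gives_zero(self, channels):
        geom = NanoTargetGeometry(MATERIALS["carbon"], target_thickness_nm=0.0)
        assert interaction_probability(channels["c12_p_3alpha"], geom, 20.0) == 0.0

    def test_linear_in_thickness(self, channels, carbon_geom):
        thick = NanoTargetGeometry(MATERIALS["carbon"], target_thickness_nm=100.0)
        p1 = interaction_probability(channels["c12_p_3alpha"], carbon_geom, 20.0)
        p2 = interaction_probability(channels["c12_p_3alpha"], thick, 20.0)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_subthreshold_is_zero(self, channels, carbon_geom):
        assert interaction_probability(channels["c12_p_3alpha"], carbon_geom, 5.0) == 0.0


class TestKinematics:
    def test_energy_conservation_in_sampled_events(self, channels):
        rng = np.random.default_rng(1)
        for name, e_p in [("c12_p_3alpha", 20.0), ("f19_p_alpha", 20.0)]:
            ch = channels[name]
            t = sample_product_energies(ch, np.full(10_000, e_p), rng)
            np.testing.assert_allclose(t.sum(axis=1), e_p + ch.q_value_mev,
                                       atol=1e-6)
            assert np.all(t >= 0)

    def test_two_body_endpoint_energies_match_closed_form(self, channels):
        """Forward/backward CM emission equals the hand-derived quadratic
        endpoints of non-relativistic two-body kinematics."""
        ch = channels["f19_p_alpha"]
        e_p = 20.0
        m_p = PARTICLE_MASS_U["p"] * MEV_PER_U
        m_f = 18.998403 * MEV_PER_U
        m_a = PARTICLE_MASS_U["alpha"] * MEV_PER_U
        m_o = PARTICLE_MASS_U["O16"] * MEV_PER_U
        # independent oracle written out from scratch
        p_lab = np.sqrt(2 * m_p * e_p)
        v_cm = p_lab / (m_p + m_f)
        t_avail = e_p + ch.q_value_mev - 0.5 * (m_a + m_o) * v_cm**2
        p_star = np.sqrt(2 * (m_a * m_o / (m_a + m_o)) * t_avail)
        for cos_t in (1.0, -1.0, 0.25):
            expect = 0.5 * m_a * ((v_cm + p_star / m_a * cos_t) ** 2
                                  + (p_star / m_a) ** 2 * (1 - cos_t**2))
            t_alpha, t_o = two_body_product_energies(ch, e_p, cos_t)
            assert t_alpha == pytest.approx(expect, rel=1e-12)
            assert t_alpha + t_o == pytest.approx(e_p + ch.q_value_mev, abs=1e-9)

    def test_three_body_mean_matches_phase_space_moment(self, channels):
        """Mean sampled alpha energy agrees with the closed-form uniform
        phase-space expectation within 3 standard errors."""
        ch = channels["c12_p_3alpha"]
        e_p = 20.0
        rng = np.random.default_rng(5)
        t = sample_product_energies(ch, np.full(10_000, e_p), rng)
        alphas = t[:, :3]
        mean = alphas.mean()
        se = alphas.mean(axis=1).std(ddof=1) / np.sqrt(len(alphas))
        assert abs(mean - phase_space_mean_alpha_energy(ch, e_p)) < 3 * se

    def test_subthreshold_sampling_rejected(self, channels):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidInputError):
            sample_alpha_event(channels["c12_p_3alpha"], 5.0, rng)

    def test_event_respects_multiplicity(self, channels):
        rng = np.random.default_rng(0)
        ev = sample_alpha_event(channels["c12_p_3alpha"], 15.0, rng)
        assert len(ev.alpha_energies) == 3
        assert sum(ev.product_energies) == pytest.approx(
            15.0 + channels["c12_p_3alpha"].q_value_mev, abs=1e-6)


class TestAlphaSpectrumPair:
    def test_no_geometry_gives_identical_pair(self, tumor_proton_spectrum):
        w, wo = alpha_spectrum_pair(tumor_proton_spectrum, None, 20_000, seed=3)
        np.testing.assert_array_equal(w.fluence, wo.fluence)

    def test_background_unchanged_by_target_presence(self, tumor_proton_spectrum,
                                                     carbon_geom):
        w, wo = alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom, 20_000, seed=3)
        _, wo_none = alpha_spectrum_pair(tumor_proton_spectrum, None, 20_000, seed=3)
        np.testing.assert_array_equal(wo.fluence, wo_none.fluence)

    def test_with_dominates_without_binwise(self, tumor_proton_spectrum, carbon_geom):
        w, wo = alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom, 50_000, seed=9)
        assert np.all(w.fluence >= wo.fluence)

    def test_carbon_excess_concentrated_1_to_6_mev(self, tumor_proton_spectrum,
                                                   carbon_geom):
        w, wo = alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom, 100_000, seed=9)
        excess = w.fluence - wo.fluence
        assert excess[1:6].sum() / excess.sum() > 0.5

    def test_total_yield_matches_poisson_expectation(self, tumor_proton_spectrum,
                                                     carbon_geom):
        n_events = 100_000
        w, wo = alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom,
                                    n_events, seed=13)
        expected = expected_alpha_yield(
            tumor_proton_spectrum, _target_channels(MATERIALS["carbon"]),
            MATERIALS["carbon"], 50e-7)
        excess = w.total_fluence - wo.total_fluence
        # forced-interaction weights: spread is the weighted-count deviation
        n_excess_counts = (w.counts - wo.counts).sum()
        sigma = expected / max(np.sqrt(n_excess_counts), 1.0)
        assert abs(excess - expected) < 3 * sigma

    def test_yield_linear_in_event_count(self, tumor_proton_spectrum, carbon_geom):
        w1, _ = alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom, 20_000, seed=2)
        w2, _ = alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom, 80_000, seed=2)
        assert np.asarray(w2.counts).sum() == pytest.approx(
            4 * np.asarray(w1.counts).sum(), rel=0.05)

    def test_requires_events(self, tumor_proton_spectrum, carbon_geom):
        with pytest.raises(InvalidInputError):
            alpha_spectrum_pair(tumor_proton_spectrum, carbon_geom, 0, seed=1)
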