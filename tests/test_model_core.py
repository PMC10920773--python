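"""Forcing functions, ODE right-hand side and the specialism fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eclip import (
    CommunityState,
    ForcingConfig,
    LifeHistoryParams,
    adsorption_multiplier,
    division_rate,
    rhs,
    specialism_fraction,
)

from conftest import random_params, random_state


def _rhs_oracle(t, y, p, fac=1.0):
    """Term-by-term scalar arithmetic, written independently of rhs()."""
    import math

    S, I, V, G = y
    mu = p.mu_ave * (1.0 + p.delta_mu * math.sin(2 * math.pi * (t + p.delta_t)))
    phi_t = p.phi * fac
    P = S + I
    division = mu * S
    s_loss = p.m_P * S * P
    infection = phi_t * S * V
    s_graze = p.psi * S * G
    i_loss = p.m_P * I * P
    lysis_out = p.eta * I
    i_graze = p.psi * I * G
    production = p.beta * p.eta * I
    adsorption = phi_t * P * V
    v_loss = p.m_V * V * V
    g_gain = p.e_eff * p.psi * P * G
    g_general = p.gamma * G
    g_loss = p.m_G * G * G
    return np.array(
        [
            division - s_loss - infection - s_graze,
            infection - i_loss - lysis_out - i_graze,
            production - adsorption - v_loss,
            g_gain + g_general - g_loss,
        ]
    )


class TestDivisionRate:
    def test_zero_amplitude_is_constant(self, params):
        p = params.replace(delta_mu=0.0, mu_ave=0.5)
        t = np.linspace(0, 3, 50)
        assert np.allclose(division_rate(t, p), 0.5)

    def test_sine_maximum(self, params):
        p = params.replace(mu_ave=0.5, delta_mu=0.2, delta_t=0.0)
        assert division_rate(0.25, p) == pytest.approx(0.6, abs=1e-12)

    @pytest.mark.parametrize("delta_mu,delta_t", [(0.0, 0.0), (0.3, 0.2), (1.0, 0.9)])
    def test_daily_mean_is_mu_ave(self, params, delta_mu, delta_t):
        p = params.replace(mu_ave=0.7, delta_mu=delta_mu, delta_t=delta_t)
        t = (np.arange(20000) + 0.5) / 20000  # midpoint rule over one day
        assert np.mean(division_rate(t, p)) == pytest.approx(0.7, abs=1e-9)

    def test_one_day_periodicity(self, params):
        t = np.linspace(0, 1, 101)
        assert np.allclose(division_rate(t, params), division_rate(t + 1.0, params))

    def test_rejects_invalid_amplitude(self):
        with pytest.raises(ValueError):
            LifeHistoryParams(
                mu_ave=0.5, delta_mu=1.2, delta_t=0.0, m_P=0, m_V=0, m_G=0,
                phi=0, psi=0, beta=1, eta=0, e_eff=0,
            )


class TestAdsorptionMultiplier:
    def test_off_is_identity(self):
        cfg = ForcingConfig(diel_adsorption=False)
        t = np.linspace(0, 2, 33)
        assert np.all(adsorption_multiplier(t, cfg) == 1.0)

    def test_dawn_is_low_dusk_is_high(self, diel_forcing):
        # t = 0 is 06:00 (midnight-to-noon half), t = 0.5 is 18:00
        assert adsorption_multiplier(0.0, diel_forcing) == 0.5
        assert adsorption_multiplier(0.5, diel_forcing) == 1.5

    def test_switch_boundaries_belong_to_starting_interval(self, diel_forcing):
        assert adsorption_multiplier(0.25, diel_forcing) == 1.5  # noon
        assert adsorption_multiplier(0.75, diel_forcing) == 0.5  # midnight
        assert adsorption_multiplier(0.25 - 1e-9, diel_forcing) == 0.5
        assert adsorption_multiplier(0.75 - 1e-9, diel_forcing) == 1.5

    def test_daily_mean_preserved(self, diel_forcing):
        t = (np.arange(4000) + 0.5) / 4000
        assert np.mean(adsorption_multiplier(t, diel_forcing)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_mean_preservation_enforced(self):
        with pytest.raises(ValueError):
            ForcingConfig(diel_adsorption=True, low_factor=0.5, high_factor=1.6)
        cfg = ForcingConfig(
            diel_adsorption=True, low_factor=0.5, high_factor=1.6,
            require_mean_preserving=False,
        )
        assert adsorption_multiplier(0.5, cfg) == 1.6


class TestRhs:
    def test_pure_exponential_limit(self, params):
        p = params.replace(m_P=0.0)
        out = rhs(0.3, CommunityState(S=1e8, I=0, V=0, G=0), p)
        mu = division_rate(0.3, p)
        assert out[0] == pytest.approx(mu * 1e8, rel=1e-14)
        assert np.all(out[1:] == 0.0)

    def test_infection_flux_conserved_between_s_and_i(self, params, rng):
        # adding infection must move cells, not create them: compare with
        # the phi = 0 derivative
        y = random_state(rng)
        with_phi = rhs(0.1, y, params)
        without = rhs(0.1, y, params.replace(phi=0.0))
        dS = with_phi[0] - without[0]
        dI = with_phi[1] - without[1]
        assert dS == pytest.approx(-params.phi * y[0] * y[2], rel=1e-12)
        assert dS == pytest.approx(-dI, rel=1e-12)

    def test_matches_term_by_term_oracle_randomised(self, rng):
        worst = 0.0
        for _ in range(1000):
            p = random_params(rng)
            y = random_state(rng)
            t = rng.uniform(0, 5)
            got = rhs(t, y, p)
            want = _rhs_oracle(t, y, p)
            denom = np.maximum(np.abs(want), 1e-30)
            worst = max(worst, np.max(np.abs(got - want) / denom))
        assert worst <= 1e-12

    def test_diel_variant_scales_infection_and_adsorption(self, params, diel_forcing, rng):
        y = random_state(rng)
        out = rhs(0.5, y, params, diel_forcing)  # dusk half: factor 1.5
        want = _rhs_oracle(0.5, y, params, fac=1.5)
        assert np.allclose(out, want, rtol=1e-12)

    def test_rejects_nonfinite_state(self, params):
        with pytest.raises(ValueError):
            rhs(0.0, np.array([np.nan, 1.0, 1.0, 1.0]), params)

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.data(),
        zero=st.integers(min_value=0, max_value=3),
    )
    def test_positivity_no_loss_from_empty_compartment(self, data, zero):
        """Every loss term vanishes with its compartment, so a zero
        component can never be driven negative."""
        seed = data.draw(st.integers(0, 2**31 - 1))
        r = np.random.default_rng(seed)
        p = random_params(r)
        y = random_state(r)
        y[zero] = 0.0
        out = rhs(r.uniform(0, 1), y, p)
        assert out[zero] >= 0.0


class TestSpecialismFraction:
    def test_pure_specialist_is_one(self, params, rng):
        states = [random_state(rng) for _ in range(5)]
        assert specialism_fraction(states, params.replace(gamma=0.0)) == 1.0

    def test_no_conversion_is_zero(self, params, rng):
        p = params.replace(e_eff=0.0, gamma=0.1)
        states = [random_state(rng) for _ in range(5)]
        assert specialism_fraction(states, p) == 0.0

    def test_equal_sources_give_half(self, params):
        # choose gamma equal to e_eff * psi * (S+I) at a constant state
        y = np.array([1e8, 0.0, 1e9, 1e6])
        gamma = params.e_eff * params.psi * 1e8
        p = params.replace(gamma=gamma)
        assert specialism_fraction([y, y], p) == pytest.approx(0.5, rel=1e-12)

    def test_all_zero_sources_error(self, params):
        p = params.replace(e_eff=0.0, gamma=0.0)
        with pytest.raises(ValueError):
            specialism_fraction([np.array([1e8, 0, 0, 0])], p)
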