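"""Integration accuracy, stationarity, extinction and observable mapping."""

import numpy as np
import pytest

from eclip import (
    CommunityState,
    ForcingConfig,
    IntegrationError,
    Trajectory,
    extinction_check,
    integrate,
    observe,
    run_to_stationary,
)

from conftest import random_state


class TestIntegrate:
    def test_exponential_closed_form(self, params):
        p = params.replace(delta_mu=0.0, m_P=0.0, mu_ave=0.4)
        init = CommunityState(S=1e7, I=0, V=0, G=0)
        t_eval = np.linspace(0, 5, 21)
        traj = integrate(p, init, (0, 5), t_eval=t_eval, rtol=1e-10)
        want = 1e7 * np.exp(0.4 * t_eval)
        assert np.allclose(traj.S, want, rtol=1e-6)

    def test_logistic_grazer_decay_closed_form(self, params):
        # gamma = 0, e_eff = 0: dG/dt = -m_G G^2 has G(t) = G0/(1+m_G G0 t)
        p = params.replace(gamma=0.0, e_eff=0.0, psi=0.0)
        G0 = 1e6
        init = CommunityState(S=0, I=0, V=0, G=G0)
        t_eval = np.linspace(0, 10, 11)
        for method in ("RK45", "fixed"):
            traj = integrate(p, init, (0, 10), t_eval=t_eval, method=method,
                             rtol=1e-10, steps_per_day=240)
            want = G0 / (1 + p.m_G * G0 * t_eval)
            assert np.allclose(traj.G, want, rtol=1e-6), method

    def test_step_halving_self_consistency(self, params, init):
        t_eval = np.linspace(0, 6, 25)
        coarse = integrate(params, init, (0, 6), t_eval=t_eval,
                           method="fixed", steps_per_day=120)
        fine = integrate(params, init, (0, 6), t_eval=t_eval,
                         method="fixed", steps_per_day=240)
        rel = np.abs(coarse.states - fine.states) / np.maximum(fine.states, 1.0)
        assert rel.max() < 1e-6

    def test_fixed_engine_matches_adaptive(self, params, init, diel_forcing):
        """Cross-validation of the two integration paths, diel forcing on."""
        t_eval = np.arange(0, 4.001, 0.25)
        fixed = integrate(params, init, (0, 4), diel_forcing, t_eval=t_eval,
                          method="fixed", steps_per_day=480)
        adaptive = integrate(params, init, (0, 4), diel_forcing, t_eval=t_eval,
                             method="RK45", rtol=1e-10, atol=1e-4)
        rel = np.abs(fixed.states - adaptive.states) / np.maximum(adaptive.states, 1.0)
        assert rel.max() < 1e-5

    def test_overflow_guard_raises(self, params, init):
        runaway = params.replace(mu_ave=1.5, delta_mu=0.0, psi=0.0, phi=0.0,
                                 m_P=0.0, m_V=0.0, m_G=0.0)
        with pytest.raises(IntegrationError, match="overflow"):
            integrate(runaway, init, (0, 50), method="fixed")

    def test_csv_roundtrip(self, params, init, tmp_path):
        traj = integrate(params, init, (0, 2), t_eval=np.linspace(0, 2, 9))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.times, traj.times)


class TestRunToStationary:
    def test_coexistence_reaches_diel_stationarity(self, params, init):
        run = run_to_stationary(params, init, burn_in=300, tol=1e-3)
        assert run.coexists and run.stationary
        assert run.max_rel_diff < 1e-3
        # the stationary state is periodic, not constant: nonzero diel range
        window = run.window
        assert np.ptp(window.pro) / window.pro.mean() > 0.01

    def test_matches_longer_burn_in(self, params, init):
        """Doubling the burn-in leaves the stationary day unchanged."""
        a = run_to_stationary(params, init, burn_in=300, samples_per_day=96)
        b = run_to_stationary(params, init, burn_in=600, samples_per_day=96)
        rel = np.abs(a.window.states - b.window.states) / np.maximum(
            b.window.states, 1.0
        )
        assert rel.max() < 1e-3

    def test_high_clearance_extinction_flagged(self, params, init):
        crash = params.replace(psi=params.psi * 50, gamma=0.5)
        run = run_to_stationary(crash, init, burn_in=300)
        assert run.extinct and run.window is None and not run.stationary

    def test_zero_burn_in_returns_first_day(self, params, init):
        run = run_to_stationary(params, init, burn_in=0, samples_per_day=96)
        direct = integrate(params, init, (0, 1), method="fixed",
                           steps_per_day=96)
        assert np.allclose(run.window.states, direct.states, rtol=1e-12)
        assert run.window.times[0] == 0.0 and run.window.times[-1] == 1.0

    def test_nighttime_peak_in_fitted_regime(self, params, init):
        """With division peaking in the evening, total cells peak at night
        (between 18:00 and 06:00, i.e. t mod 1 in [0.5, 1))."""
        run = run_to_stationary(params, init, burn_in=300)
        tm = run.window.times % 1.0
        t_peak = tm[np.argmax(run.window.pro)]
        assert 0.5 <= t_peak < 1.0


class TestExtinctionCheck:
    def _traj(self, pro_values):
        n = len(pro_values)
        states = np.zeros((n, 4))
        states[:, 0] = pro_values
        return Trajectory(np.arange(n, dtype=float), states)

    def test_abundant_is_false(self):
        assert extinction_check(self._traj([1e7, 2e7])) is False

    def test_below_floor_is_true(self):
        assert extinction_check(self._traj([1e7, 0.5])) is True

    def test_boundary_is_strict(self):
        assert extinction_check(self._traj([1.0, 2.0])) is False


class TestObserve:
    def test_basic_mapping(self):
        states = np.array([[9e7, 1e7, 5e9, 2e6]])
        obs = observe(Trajectory(np.array([0.0]), states))
        assert obs.pro[0] == 1e8
        assert obs.infected_pct[0] == pytest.approx(10.0)
        assert obs.virus[0] == 5e9 and obs.grazer[0] == 2e6

    def test_no_cells_convention(self):
        states = np.array([[0.0, 0.0, 1e9, 1e6]])
        obs = observe(Trajectory(np.array([0.0]), states))
        assert obs.infected_pct[0] == 0.0

    def test_algebraic_inversion_roundtrip(self, rng):
        states = np.abs(rng.lognormal(18, 1, size=(50, 4)))
        obs = observe(Trajectory(np.arange(50.0), states))
        S = obs.pro * (1 - obs.infected_pct / 100)
        I = obs.pro * obs.infected_pct / 100
        assert np.allclose(S, states[:, 0], rtol=1e-12)
        assert np.allclose(I, states[:, 1], rtol=1e-12)
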