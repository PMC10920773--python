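"""Observation CSV round-trips and the detrending contract."""

import logging

import numpy as np
import pandas as pd
import pytest

from eclip import (
    ObservationSet,
    SignalSeries,
    detrend,
    fit_trend,
    fit_trends,
    read_observations,
    retrend,
    write_observations,
)
from eclip.observations import SIGNALS


def _simple_obs(duration=12.0):
    t4 = np.arange(0, duration + 1e-9, 4 / 24)
    th = np.arange(0, duration + 1e-9, 1 / 24)
    return ObservationSet(
        pro=SignalSeries(th, 1e8 + 5e6 * np.sin(2 * np.pi * th)),
        infected_pct=SignalSeries(t4, 1.5 + 0.2 * np.cos(2 * np.pi * t4)),
        virus=SignalSeries(t4, 1e9 + 1e7 * t4),
        grazer=SignalSeries(t4, 1e6 * np.ones_like(t4)),
    )


class TestReadWrite:
    def test_roundtrip(self, tmp_path):
        obs = _simple_obs()
        path = tmp_path / "obs.csv"
        write_observations(obs, path)
        back = read_observations(path)
        for name in SIGNALS:
            assert np.allclose(back[name].times, obs[name].times)
            assert np.allclose(back[name].values, obs[name].values)

    def test_nan_rows_dropped_with_warning(self, tmp_path, caplog):
        obs = _simple_obs()
        df = obs.to_dataframe()
        df.loc[3, "value"] = np.nan
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        with caplog.at_level(logging.WARNING, logger="eclip.observations"):
            back = read_observations(path)
        assert "dropping 1 rows" in caplog.text
        total = sum(len(back[s]) for s in SIGNALS)
        assert total == len(df) - 1

    def test_negative_abundance_rejected(self, tmp_path):
        obs = _simple_obs()
        df = obs.to_dataframe()
        df.loc[df.index[-1], "value"] = -5.0
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative"):
            read_observations(path)

    def test_unknown_signal_rejected(self, tmp_path):
        path = tmp_path / "obs.csv"
        pd.DataFrame(
            {"time_days": [0.0], "signal": ["chlorophyll"], "value": [1.0]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="unknown signal"):
            read_observations(path)

    def test_unknown_column_rejected(self, tmp_path):
        df = _simple_obs().to_dataframe()
        df["depth"] = 15.0
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="unknown columns"):
            read_observations(path)


class TestTrendFit:
    def test_exactly_linear_series_has_zero_residuals(self):
        t = np.linspace(0, 12, 40)
        s = SignalSeries(t, 3.0 + 2.0 * t)
        trend = fit_trend(s, "linear")
        assert np.allclose(trend.residual, 0.0, atol=1e-9)
        assert trend.slope == pytest.approx(2.0)

    def test_constant_series_zero_slope(self):
        t = np.linspace(0, 12, 40)
        trend = fit_trend(SignalSeries(t, np.full(40, 7.0)), "linear")
        assert trend.slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(trend.residual, 0.0, atol=1e-10)

    def test_recovers_slope_under_sine_and_noise(self, rng):
        # oracle: closed-form OLS slope standard error on the same design
        t = np.arange(0, 12, 1 / 24)
        slope, sigma = 4.0, 1.5
        y = 10 + slope * t + 2.0 * np.sin(2 * np.pi * t) + rng.normal(0, sigma, t.size)
        trend = fit_trend(SignalSeries(t, y), "linear")
        resid_sd = np.std(y - trend.predict(t), ddof=2)
        se = resid_sd / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(trend.slope - slope) < 2 * se

    def test_degenerate_grid_rejected(self):
        s = SignalSeries.__new__(SignalSeries)
        s.times = np.array([1.0, 1.0, 1.0])
        s.values = np.array([1.0, 2.0, 3.0])
        s.sigma = None
        with pytest.raises(ValueError, match="degenerate|increasing"):
            fit_trend(s, "linear")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            fit_trend(SignalSeries(np.array([0.0, 1.0]), np.array([1.0, 2.0])))


class TestDetrendRetrend:
    @pytest.mark.parametrize("family", ["constant", "linear", "quadratic", "lowess"])
    def test_roundtrip_identity(self, family, rng):
        t = np.arange(0, 12, 1 / 6)
        y = 1e8 * rng.lognormal(0, 0.2, t.size)
        s = SignalSeries(t, y)
        trend = fit_trend(s, family)
        back = retrend(detrend(s, trend), trend)
        assert np.max(np.abs(back.values - y) / np.abs(y)) < 1e-10

    def test_residual_projection_is_exact(self, rng):
        """Detrending removes the fitted family exactly: residuals are
        orthogonal to the design."""
        t = np.arange(0, 12, 1 / 6)
        y = rng.normal(50, 5, t.size) + 3 * t
        s = SignalSeries(t, y)
        trend = fit_trend(s, "linear")
        r = detrend(s, trend).values
        X = np.column_stack([np.ones_like(t), t])
        assert np.max(np.abs(X.T @ r)) / np.max(np.abs(X.T @ y)) < 1e-10

    def test_constant_family_subtracts_mean(self, rng):
        t = np.arange(0, 12, 0.5)
        y = rng.normal(10, 1, t.size)
        s = SignalSeries(t, y)
        trend = fit_trend(s, "constant")
        assert np.allclose(detrend(s, trend).values, y - y.mean())

    def test_model_series_onto_observation_grid(self, params, init):
        """Fig-2-style pipeline: add the fitted data trend onto model
        output evaluated on the observation grid."""
        from eclip import integrate, observe

        obs = _simple_obs()
        trends = fit_trends(obs, "linear")
        traj = integrate(params, init, (0, 12), t_eval=obs.virus.times,
                         method="fixed", steps_per_day=96)
        model_virus = SignalSeries(obs.virus.times, observe(traj).virus)
        vis = retrend(model_virus, trends["virus"])
        assert vis.values.shape == obs.virus.values.shape
        assert np.allclose(
            vis.values - model_virus.values,
            trends["virus"].predict(obs.virus.times),
        )
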