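"""Observation CSV handling and the detrended-fitting convention.

Field campaigns sample the four signals on different grids (near-continuous
flow-cytometry cell counts; 4-hourly bottle samples for infected cells,
free viruses and nanoflagellates), so observations are stored in a long
("tidy") CSV with columns ``time_days, signal, value`` and an optional
``sigma`` column.  Times are days since 06:00 local on day 0.

Each signal carries a slow multi-day trend on top of its diel oscillation.
Models are fitted against detrended data; for visualisation the fitted
trend is added back onto model output.  The default trend family is an
ordinary least-squares straight line per signal, fitted independently;
constant, quadratic and lowess families are also available.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SIGNALS",
    "SignalSeries",
    "ObservationSet",
    "TrendModel",
    "read_observations",
    "write_observations",
    "fit_trend",
    "fit_trends",
    "detrend",
    "retrend",
    "detrend_observations",
]

SIGNALS = ("pro", "infected_pct", "virus", "grazer")

_POLY_ORDER = {"constant": 0, "linear": 1, "quadratic": 2}


@dataclass
class SignalSeries:
    """One signal's samples: times (days) and values, optional uncertainties."""

    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise ValueError("sigma must match times in length")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ObservationSet:
    """The four observed signals, each on its own time grid."""

    pro: SignalSeries
    infected_pct: SignalSeries
    virus: SignalSeries
    grazer: SignalSeries

    def __getitem__(self, signal: str) -> SignalSeries:
        if signal not in SIGNALS:
            raise KeyError(signal)
        return getattr(self, signal)

    def signals(self):
        return {s: self[s] for s in SIGNALS}

    @property
    def duration(self) -> float:
        return max(float(self[s].times[-1]) for s in SIGNALS if len(self[s]))

    def validate(self) -> "ObservationSet":
        """Range checks for raw (not detrended) observations."""
        for name in SIGNALS:
            s = self[name]
            if len(s) == 0:
                raise ValueError(f"signal {name!r} has no samples")
            if not np.all(np.isfinite(s.values)):
                raise ValueError(f"non-finite values in signal {name!r}")
            if np.any(s.values < 0):
                raise ValueError(f"negative abundance in signal {name!r}")
            if np.any(s.times < 0):
                raise ValueError(f"negative sample time in signal {name!r}")
        if np.any(self.infected_pct.values > 100):
            raise ValueError("infected_pct above 100%")
        return self

    def fingerprint(self) -> str:
        """Content hash used to guard against mixing datasets across fits."""
        h = hashlib.sha256()
        for name in SIGNALS:
            s = self[name]
            h.update(name.encode())
            h.update(np.ascontiguousarray(s.times).tobytes())
            h.update(np.ascontiguousarray(s.values).tobytes())
        return h.hexdigest()[:16]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for name in SIGNALS:
            s = self[name]
            df = pd.DataFrame(
                {"time_days": s.times, "signal": name, "value": s.values}
            )
            if s.sigma is not None:
                df["sigma"] = s.sigma
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_observations(path) -> ObservationSet:
    """Read a long-format observation CSV.

    Rows with missing values are dropped (count logged); unknown signal
    names, non-monotonic times and negative abundances are errors.
    """
    df = pd.read_csv(path)
    required = {"time_days", "signal", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    extra = set(df.columns) - required - {"sigma"}
    if extra:
        raise ValueError(f"unknown columns in observation CSV: {sorted(extra)}")
    unknown = set(df["signal"].unique()) - set(SIGNALS)
    if unknown:
        raise ValueError(f"unknown signal names: {sorted(unknown)}")
    n_bad = int(df[["time_days", "value"]].isna().any(axis=1).sum())
    if n_bad:
        logger.warning("dropping %d rows with missing values", n_bad)
        df = df.dropna(subset=["time_days", "value"])
    series = {}
    for name in SIGNALS:
        sub = df[df["signal"] == name].sort_values("time_days")
        if sub.empty:
            raise ValueError(f"signal {name!r} absent from {path}")
        sigma = None
        if "sigma" in sub.columns and sub["sigma"].notna().all():
            sigma = sub["sigma"].to_numpy()
        series[name] = SignalSeries(
            sub["time_days"].to_numpy(), sub["value"].to_numpy(), sigma
        )
    return ObservationSet(**series).validate()


def write_observations(obs: ObservationSet, path) -> None:
    obs.to_csv(path)


@dataclass
class TrendModel:
    """Fitted slow trend for one signal.

    ``family`` is one of constant / linear / quadratic (``coef`` holds
    ascending polynomial coefficients in time) or lowess (``grid`` and
    ``fitted`` hold the smoother evaluated on the training grid, predicted
    elsewhere by interpolation).  ``residual`` is the detrended training
    series.
    """

    family: str
    coef: np.ndarray | None = None
    grid: np.ndarray | None = None
    fitted: np.ndarray | None = None
    residual: np.ndarray | None = None

    def predict(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.family in _POLY_ORDER:
            return np.polynomial.polynomial.polyval(times, self.coef)
        if self.family == "lowess":
            return np.interp(times, self.grid, self.fitted)
        raise ValueError(f"unknown trend family {self.family!r}")

    @property
    def slope(self) -> float:
        """Linear slope, units of the signal per day (0 for constant)."""
        if self.family not in _POLY_ORDER:
            raise ValueError("slope only defined for polynomial families")
        return float(self.coef[1]) if len(self.coef) > 1 else 0.0


def fit_trend(series: SignalSeries, family: str = "linear", lowess_frac: float = 0.5) -> TrendModel:
    """Least-squares fit of a slow trend to one signal."""
    t, y = series.times, series.values
    if len(series) < 3:
        raise ValueError("need at least 3 samples to fit a trend")
    if family in _POLY_ORDER:
        order = _POLY_ORDER[family]
        if np.ptp(t) == 0 and order > 0:
            raise ValueError("degenerate time grid: all sample times equal")
        coef = np.polynomial.polynomial.polyfit(t, y, order)
        model = TrendModel(family=family, coef=coef)
    elif family == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm = lowess(y, t, frac=lowess_frac, return_sorted=True)
        model = TrendModel(family="lowess", grid=sm[:, 0], fitted=sm[:, 1])
    else:
        raise ValueError(f"unknown trend family {family!r}")
    model.residual = y - model.predict(t)
    return model


def fit_trends(obs: ObservationSet, family: str = "linear") -> dict[str, TrendModel]:
    """Fit a trend of the same family to each signal independently."""
    return {name: fit_trend(obs[name], family) for name in SIGNALS}


def detrend(series: SignalSeries, trend: TrendModel) -> SignalSeries:
    """Subtract the fitted trend; the result is sign-indefinite."""
    return replace(series, values=series.values - trend.predict(series.times))


def retrend(series: SignalSeries, trend: TrendModel) -> SignalSeries:
    """Add the fitted data trend back onto (model) output for visualisation."""
    return replace(series, values=series.values + trend.predict(series.times))


def detrend_observations(
    obs: ObservationSet, trends: dict[str, TrendModel]
) -> ObservationSet:
    return ObservationSet(
        **{name: detrend(obs[name], trends[name]) for name in SIGNALS}
    )
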