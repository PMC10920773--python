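"""Trajectory integration, burn-in to stationary dynamics, and observables.

Two integration paths are provided.  ``method="RK45"`` (or any scipy
``solve_ivp`` method) integrates adaptively, piecewise between the diel
forcing discontinuities so the step controller never sees a jump.  The
``"fixed"`` method uses the jitted fixed-step RK4 kernel, which is orders
of magnitude faster and is the default engine for inference and parameter
sweeps; the two paths are cross-validated in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _engine
from .model import adsorption_multiplier, rhs
from .params import CommunityState, ForcingConfig, LifeHistoryParams

__all__ = [
    "Trajectory",
    "ObservableSeries",
    "StationaryRun",
    "IntegrationError",
    "integrate",
    "run_to_stationary",
    "extinction_check",
    "observe",
]

#: Abundances above this (per litre) abort integration: they signal a
#: runaway parameter combination, not plausible ocean states.
OVERFLOW_GUARD = 1e15

#: Default extinction floor, cells per litre.
EXTINCTION_FLOOR = 1.0


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Integrated model solution: ``states[i]`` = (S, I, V, G) at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray
    params: LifeHistoryParams | None = None
    forcing: ForcingConfig | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def I(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def pro(self) -> np.ndarray:
        """Total *Prochlorococcus*, S + I."""
        return self.S + self.I

    def at(self, times) -> np.ndarray:
        """Linearly interpolated states on an arbitrary grid."""
        times = np.asarray(times, dtype=float)
        return np.column_stack(
            [np.interp(times, self.times, self.states[:, c]) for c in range(4)]
        )

    def window(self, t_lo: float, t_hi: float) -> "Trajectory":
        m = (self.times >= t_lo - 1e-12) & (self.times <= t_hi + 1e-12)
        return Trajectory(self.times[m], self.states[m], self.params, self.forcing)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "S": self.S,
                "I": self.I,
                "V": self.V,
                "G": self.G,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_days"].to_numpy(), df[["S", "I", "V", "G"]].to_numpy())


@dataclass
class ObservableSeries:
    """Model state mapped to the four observed signals."""

    times: np.ndarray
    pro: np.ndarray
    infected_pct: np.ndarray
    virus: np.ndarray
    grazer: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "pro": self.pro,
                "infected_pct": self.infected_pct,
                "virus": self.virus,
                "grazer": self.grazer,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _validate_output(states: np.ndarray, atol: float) -> np.ndarray:
    bad = states < -atol
    if np.any(bad):
        raise IntegrationError(
            f"state went negative beyond solver tolerance (min {states.min():.3g})"
        )
    states = np.where((states < 0) & (states > -atol), 0.0, states)
    if np.any(states > OVERFLOW_GUARD):
        raise IntegrationError(
            f"abundance exceeded overflow guard {OVERFLOW_GUARD:g} per L"
        )
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state in solution")
    return states


def _integrate_adaptive(params, y0, t0, t1, forcing, t_eval, method, rtol, atol):
    diel = forcing is not None and forcing.diel_adsorption
    # split at quarter-day forcing switches so the step controller never
    # crosses a discontinuity
    if diel:
        first = math.floor(t0 * 4) / 4
        breaks = [b / 4 for b in range(int(first * 4), math.ceil(t1 * 4) + 1)]
        edges = [t0] + [b for b in breaks if t0 < b < t1] + [t1]
    else:
        edges = [t0, t1]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = y0.copy()
    for a, b in zip(edges[:-1], edges[1:]):
        fac = adsorption_multiplier(0.5 * (a + b), forcing)
        eff = params.replace(phi=params.phi * fac)

        def fun(t, y, _p=eff):
            return rhs(t, y, _p, None)

        sol = solve_ivp(
            fun, (a, b), y, method=method, rtol=rtol, atol=atol, dense_output=True
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        if t_eval is None:
            sel = sol.t < b if b < t1 else slice(None)
            times_out.append(sol.t[sel])
            states_out.append(sol.y[:, sel].T)
        else:
            pts = t_eval[(t_eval >= a) & (t_eval < b)]
            if b == t1:
                pts = t_eval[(t_eval >= a) & (t_eval <= b)]
            if pts.size:
                times_out.append(pts)
                states_out.append(sol.sol(pts).T)
    times = np.concatenate(times_out)
    states = np.concatenate(states_out)
    return times, states


def _integrate_fixed(params, y0, t0, t1, forcing, t_eval, steps_per_day, atol):
    spd = int(steps_per_day)
    n_steps_f = (t1 - t0) * spd
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-6:
        raise ValueError("t_span must be a whole number of steps for method='fixed'")
    diel = forcing is not None and forcing.diel_adsorption
    if diel:
        if spd % 4 != 0:
            raise ValueError("steps_per_day must be a multiple of 4 with diel forcing")
        base = (t0 % 1.0) * spd
        if abs(base - round(base)) > 1e-6:
            raise ValueError("t0 must lie on the step grid with diel forcing")
    if t_eval is None:
        t_eval = t0 + np.arange(n_steps + 1) / spd
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    idx_f = (t_eval - t0) * spd
    out_idx = np.rint(idx_f).astype(np.int64)
    if np.max(np.abs(idx_f - out_idx)) > 1e-6:
        raise ValueError("t_eval points must lie on the fixed step grid")
    low = forcing.low_factor if forcing is not None else 0.5
    high = forcing.high_factor if forcing is not None else 1.5
    states, status, fail_step = _engine.rk4_run(
        y0, params.to_array(), float(t0), n_steps, spd, out_idx,
        diel, low, high, atol, OVERFLOW_GUARD,
    )
    if status != _engine.STATUS_OK:
        reason = {
            _engine.STATUS_OVERFLOW: "overflow guard exceeded",
            _engine.STATUS_NEGATIVE: "negative state beyond tolerance",
            _engine.STATUS_NONFINITE: "non-finite state",
        }[status]
        raise IntegrationError(
            f"fixed-step integration aborted at t = {t0 + fail_step / spd:.4g}: {reason}"
        )
    return t_eval, states


def integrate(
    params: LifeHistoryParams,
    init: CommunityState,
    t_span: tuple[float, float],
    forcing: ForcingConfig | None = None,
    t_eval=None,
    method: str = "RK45",
    rtol: float = 1e-8,
    atol: float = 1e-2,
    steps_per_day: int = 240,
) -> Trajectory:
    """Integrate the community ODE over ``t_span`` (days).

    ``method`` is any scipy ``solve_ivp`` method name, or ``"fixed"`` for
    the fixed-step RK4 engine (``steps_per_day`` steps per day; requested
    ``t_eval`` points must then lie on the step grid).  ``atol`` doubles as
    the negativity clip threshold: undershoot smaller than ``atol`` in
    magnitude is treated as solver noise and set to zero, anything larger
    raises :class:`IntegrationError`.
    """
    t0, t1 = map(float, t_span)
    if not (np.isfinite(t0) and np.isfinite(t1)) or t1 <= t0:
        raise ValueError(f"invalid t_span {t_span!r}")
    y0 = init.to_array() if isinstance(init, CommunityState) else np.asarray(init, float)
    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval.size and (t_eval[0] < t0 - 1e-12 or t_eval[-1] > t1 + 1e-12):
            raise ValueError("t_eval outside t_span")
    if method == "fixed":
        times, states = _integrate_fixed(
            params, y0, t0, t1, forcing, t_eval, steps_per_day, atol
        )
    else:
        times, states = _integrate_adaptive(
            params, y0, t0, t1, forcing, t_eval, method, rtol, atol
        )
    states = _validate_output(states, atol)
    return Trajectory(times, states, params, forcing)


@dataclass
class StationaryRun:
    """Outcome of a burn-in run: the post-burn-in day and its diagnostics."""

    window: Trajectory | None
    stationary: bool
    extinct: bool
    max_rel_diff: float = field(default=np.nan)

    @property
    def coexists(self) -> bool:
        return not self.extinct


def run_to_stationary(
    params: LifeHistoryParams,
    init: CommunityState,
    forcing: ForcingConfig | None = None,
    burn_in: float = 1000.0,
    tol: float = 1e-3,
    samples_per_day: int = 240,
    method: str = "fixed",
    extinction_floor: float = EXTINCTION_FLOOR,
) -> StationaryRun:
    """Integrate through a transient and return the first post-burn-in day.

    Two further days are simulated beyond ``burn_in``; the run is flagged
    stationary when the state one day apart differs by less than ``tol``
    in relative terms everywhere on the comparison window (the dynamics
    are diel-periodic, not constant, so the comparison is at lag 1 day).
    If total *Prochlorococcus* drops below ``extinction_floor`` anywhere,
    the run is flagged extinct and no window is returned.
    """
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    total = burn_in + 2.0
    try:
        traj = integrate(
            params,
            init,
            (0.0, total),
            forcing,
            method=method,
            steps_per_day=samples_per_day,
        )
    except IntegrationError:
        # runaway or collapsing dynamics; treat collapse as extinction
        return StationaryRun(None, False, True)
    if extinction_check(traj, extinction_floor):
        return StationaryRun(None, False, True)
    day = samples_per_day
    grid = burn_in + np.arange(2 * day + 1) / day
    two = traj.states[-(2 * day + 1):] if method == "fixed" else traj.at(grid)
    first, second = two[: day + 1], two[day:]
    rel = np.abs(second - first) / np.maximum(np.abs(first), 1.0)
    max_rel = float(np.max(rel))
    window = Trajectory(grid[: day + 1], two[: day + 1], params, forcing)
    return StationaryRun(window, bool(max_rel < tol), False, max_rel)


def extinction_check(trajectory: Trajectory, floor: float = EXTINCTION_FLOOR) -> bool:
    """True iff total *Prochlorococcus* S+I falls strictly below ``floor``."""
    if trajectory.times.size == 0:
        raise ValueError("empty trajectory")
    return bool(np.min(trajectory.pro) < floor)


def observe(trajectory: Trajectory) -> ObservableSeries:
    """Map model state to the four observed signals.

    ``pro`` = S + I; ``infected_pct`` = 100 I / (S+I) (zero by convention
    when there are no cells); ``virus`` = V; ``grazer`` = G.
    """
    P = trajectory.pro
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(P > 0, 100.0 * trajectory.I / np.where(P > 0, P, 1.0), 0.0)
    return ObservableSeries(
        times=trajectory.times.copy(),
        pro=P,
        infected_pct=pct,
        virus=trajectory.V.copy(),
        grazer=trajectory.G.copy(),
    )
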