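"""Parameter sensitivity of the magnitude and source of cell mortality.

Each swept parameter is varied from 0.25x to 4x its baseline value with
everything else held fixed; for every multiplier the model is run through
a long burn-in (default 1000 days) to reach stationary diel dynamics and
the mortality partition is evaluated on the post-burn-in day.  Parameter
combinations that drive total *Prochlorococcus* below 1 cell per litre
are recorded as extinctions rather than errors, and masked in grids.

Local effect directions at the baseline group the parameters into three
"arcs": a growth arc (raises daily mortality, barely moves the
lysis:grazing ratio), a viral arc (raises the ratio) and a grazer arc
(lowers it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mortality import partition
from .params import CommunityState, ForcingConfig, LifeHistoryParams
from .simulate import run_to_stationary

__all__ = [
    "SWEEP_PARAMETERS",
    "SweepResult",
    "GridResult",
    "default_multipliers",
    "sweep_single",
    "sweep_pair",
    "arc_classification",
]

#: Parameters included in single-parameter sweeps.
SWEEP_PARAMETERS = (
    "mu_ave", "delta_mu", "delta_t", "m_P", "m_V", "m_G", "phi", "psi", "beta", "eta",
)


def default_multipliers(n: int = 33) -> np.ndarray:
    """Log-spaced multipliers over [0.25, 4]; the midpoint is exactly 1."""
    if n < 3 or n % 2 == 0:
        raise ValueError("n must be odd and >= 3 so the grid contains 1.0")
    grid = np.geomspace(0.25, 4.0, n)
    grid[n // 2] = 1.0
    return grid


@dataclass
class SweepResult:
    """Stationary mortality metrics along one parameter's multiplier grid."""

    parameter: str
    multipliers: np.ndarray
    m_total_daily: np.ndarray
    lysis_to_grazing: np.ndarray
    coexistence: np.ndarray  # bool per grid point
    baseline: LifeHistoryParams

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "multiplier": self.multipliers,
                "m_total_daily": self.m_total_daily,
                "lysis_to_grazing": self.lysis_to_grazing,
                "coexistence": self.coexistence,
            }
        )


@dataclass
class GridResult:
    """Mortality metrics over a factorial adsorption x clearance grid."""

    phi_multipliers: np.ndarray
    psi_multipliers: np.ndarray
    m_total_daily: np.ndarray  # shape (len(phi), len(psi))
    lysis_to_grazing: np.ndarray
    extinct: np.ndarray  # bool mask, same shape
    baseline: LifeHistoryParams

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, fm in enumerate(self.phi_multipliers):
            for j, pm in enumerate(self.psi_multipliers):
                rows.append(
                    {
                        "phi_multiplier": fm,
                        "psi_multiplier": pm,
                        "m_total_daily": self.m_total_daily[i, j],
                        "lysis_to_grazing": self.lysis_to_grazing[i, j],
                        "extinct": bool(self.extinct[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        return {
            "baseline_params": self.baseline.to_dict(),
            "phi_multipliers": list(map(float, self.phi_multipliers)),
            "psi_multipliers": list(map(float, self.psi_multipliers)),
        }


def _evaluate(params, init, forcing, burn_in, samples_per_day, tol):
    """(m_total_daily, lysis_to_grazing, coexists) at stationarity."""
    run = run_to_stationary(
        params, init, forcing, burn_in=burn_in,
        samples_per_day=samples_per_day, tol=tol,
    )
    if run.extinct:
        return np.nan, np.nan, False
    part = partition(run.window, params)
    return part.m_total_daily, part.lysis_to_grazing, True


def sweep_single(
    baseline: LifeHistoryParams,
    parameter: str,
    multipliers=None,
    init: CommunityState | None = None,
    forcing: ForcingConfig | None = None,
    burn_in: float = 1000.0,
    samples_per_day: int = 96,
    stationarity_tol: float = 1e-3,
) -> SweepResult:
    """Vary one parameter over its multiplier grid, all others fixed."""
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(
            f"parameter must be one of {SWEEP_PARAMETERS}, got {parameter!r}"
        )
    mult = np.asarray(
        default_multipliers() if multipliers is None else multipliers, dtype=float
    )
    if not np.any(np.isclose(mult, 1.0)):
        raise ValueError("multiplier grid must include the baseline value 1.0")
    if init is None:
        from .synthetic import DEFAULT_INIT

        init = DEFAULT_INIT
    base_val = getattr(baseline, parameter)
    m_tot = np.empty(mult.size)
    ratio = np.empty(mult.size)
    coex = np.empty(mult.size, dtype=bool)
    for k, m in enumerate(mult):
        value = base_val * m
        if parameter == "delta_mu":
            value = min(value, 1.0)
        if parameter == "delta_t":
            value = value % 1.0
        params = baseline.replace(**{parameter: value})
        m_tot[k], ratio[k], coex[k] = _evaluate(
            params, init, forcing, burn_in, samples_per_day, stationarity_tol
        )
    return SweepResult(parameter, mult, m_tot, ratio, coex, baseline)


def sweep_pair(
    baseline: LifeHistoryParams,
    phi_multipliers=None,
    psi_multipliers=None,
    init: CommunityState | None = None,
    forcing: ForcingConfig | None = None,
    burn_in: float = 1000.0,
    samples_per_day: int = 96,
    stationarity_tol: float = 1e-3,
) -> GridResult:
    """Covary adsorption and clearance multipliers on a factorial grid."""
    phi_m = np.asarray(
        default_multipliers() if phi_multipliers is None else phi_multipliers,
        dtype=float,
    )
    psi_m = np.asarray(
        default_multipliers() if psi_multipliers is None else psi_multipliers,
        dtype=float,
    )
    for grid, name in ((phi_m, "phi"), (psi_m, "psi")):
        if not np.any(np.isclose(grid, 1.0)):
            raise ValueError(f"{name} multiplier grid must include 1.0")
    if init is None:
        from .synthetic import DEFAULT_INIT

        init = DEFAULT_INIT
    m_tot = np.empty((phi_m.size, psi_m.size))
    ratio = np.empty_like(m_tot)
    extinct = np.zeros(m_tot.shape, dtype=bool)
    for i, fm in enumerate(phi_m):
        for j, pm in enumerate(psi_m):
            params = baseline.replace(
                phi=baseline.phi * fm, psi=baseline.psi * pm
            )
            m, r, coex = _evaluate(
                params, init, forcing, burn_in, samples_per_day, stationarity_tol
            )
            m_tot[i, j], ratio[i, j] = m, r
            extinct[i, j] = not coex
    return GridResult(phi_m, psi_m, m_tot, ratio, extinct, baseline)


def arc_classification(
    sweeps: dict[str, SweepResult],
    elasticity_tol: float = 0.1,
) -> pd.DataFrame:
    """Group swept parameters into growth / viral / grazer arcs.

    Elasticities d ln(m_total)/d ln(multiplier) and d ln(ratio)/d ln(mult)
    are estimated by central finite differences at multiplier 1.  A
    parameter that moves neither axis beyond ``elasticity_tol`` is
    'insensitive'.  Otherwise the growth arc collects parameters whose
    (positive) mortality response dominates their ratio response by at
    least a factor of two — raising losses without substantively shifting
    their composition — while the remaining parameters are sorted by the
    sign of the ratio response: positive marks the viral arc, negative the
    grazer arc.
    """
    rows = []
    for name, sw in sweeps.items():
        k = int(np.argmin(np.abs(sw.multipliers - 1.0)))
        if k == 0 or k == sw.multipliers.size - 1:
            raise ValueError("baseline multiplier must be interior to the grid")
        if not (sw.coexistence[k - 1] and sw.coexistence[k] and sw.coexistence[k + 1]):
            raise ValueError(
                f"baseline neighbourhood of {name!r} does not coexist"
            )
        dlnm = np.log(sw.multipliers[k + 1] / sw.multipliers[k - 1])
        e_mort = np.log(sw.m_total_daily[k + 1] / sw.m_total_daily[k - 1]) / dlnm
        e_ratio = np.log(
            sw.lysis_to_grazing[k + 1] / sw.lysis_to_grazing[k - 1]
        ) / dlnm
        if abs(e_ratio) < elasticity_tol and abs(e_mort) < elasticity_tol:
            arc = "insensitive"
        elif e_mort > 0 and abs(e_mort) >= 2.0 * abs(e_ratio):
            arc = "growth"
        elif e_ratio > 0:
            arc = "viral"
        else:
            arc = "grazer"
        rows.append(
            {
                "parameter": name,
                "elasticity_mortality": e_mort,
                "elasticity_ratio": e_ratio,
                "sign_mortality": int(np.sign(e_mort)) if abs(e_mort) >= elasticity_tol else 0,
                "sign_ratio": int(np.sign(e_ratio)) if abs(e_ratio) >= elasticity_tol else 0,
                "arc": arc,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def save_sweeps(sweeps: dict[str, SweepResult], csv_path, manifest_path=None) -> None:
    """Tidy long-format CSV plus a JSON manifest of the baseline."""
    df = pd.concat([s.to_dataframe() for s in sweeps.values()], ignore_index=True)
    df.to_csv(csv_path, index=False)
    if manifest_path is not None:
        any_sweep = next(iter(sweeps.values()))
        manifest = {
            "baseline_params": any_sweep.baseline.to_dict(),
            "parameters": sorted(sweeps),
            "multipliers": list(map(float, any_sweep.multipliers)),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
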