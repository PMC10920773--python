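"""Right-hand side of the community ODE and its diel forcing terms.

The model couples susceptible (S) and infected (I) *Prochlorococcus*,
free cyanophage (V) and heterotrophic nanoflagellate grazers (G):

    dS/dt = mu(t) S - m_P S (S+I) - phi(t) S V - psi S G
    dI/dt = phi(t) S V - m_P I (S+I) - eta I - psi I G
    dV/dt = beta eta I - phi(t) (S+I) V - m_V V^2
    dG/dt = e_eff psi (S+I) G + gamma G - m_G G^2

with a sinusoidal light-driven division rate

    mu(t) = mu_ave (1 + delta_mu sin(2 pi (t + delta_t)))

and, in the diel-adsorption variant, a step-function adsorption rate
phi(t) = phi * adsorption_multiplier(t) that is low from midnight to noon
and high from noon to midnight.  Grazing is indiscriminate between S and I;
quadratic loss terms close the system without favouring either predator.
"""

from __future__ import annotations

import numpy as np

from .params import CommunityState, ForcingConfig, LifeHistoryParams

__all__ = [
    "division_rate",
    "adsorption_multiplier",
    "rhs",
    "specialism_fraction",
]


def division_rate(t, params: LifeHistoryParams):
    """Diel division rate mu(t) = mu_ave (1 + delta_mu sin(2 pi (t + delta_t))).

    ``t`` is in days (scalar or array); the result is in day^-1 and is
    1-day periodic with mean ``mu_ave``.
    """
    if not 0.0 <= params.delta_mu <= 1.0:
        raise ValueError("delta_mu outside [0, 1] gives a negative division rate")
    t = np.asarray(t, dtype=float)
    out = params.mu_ave * (
        1.0 + params.delta_mu * np.sin(2.0 * np.pi * (t + params.delta_t))
    )
    return out if out.ndim else float(out)


def adsorption_multiplier(t, config: ForcingConfig | None = None):
    """Diel step multiplier on the adsorption rate.

    Returns 1 everywhere when diel adsorption is off.  When on, returns
    ``low_factor`` on the midnight-to-noon half of the day and
    ``high_factor`` on the noon-to-midnight half.  With t = 0 at 06:00,
    noon is t mod 1 = 0.25 and midnight is t mod 1 = 0.75, so the high
    interval is t mod 1 in [0.25, 0.75); boundary instants belong to the
    interval that begins there.
    """
    t = np.asarray(t, dtype=float)
    if config is None or not config.diel_adsorption:
        out = np.ones_like(t)
        return out if out.ndim else float(out)
    tm = np.mod(t, 1.0)
    out = np.where(
        (tm >= 0.25) & (tm < 0.75), config.high_factor, config.low_factor
    )
    return out if out.ndim else float(out)


def rhs(
    t: float,
    state,
    params: LifeHistoryParams,
    forcing: ForcingConfig | None = None,
) -> np.ndarray:
    """Time derivatives (dS, dI, dV, dG), per litre per day.

    ``state`` may be a :class:`CommunityState` or a length-4 array
    (S, I, V, G).  The same time-dependent phi(t) multiplies both the
    infection flux into I and the adsorption sink on V: they are one and
    the same adsorption process.
    """
    y = state.to_array() if isinstance(state, CommunityState) else np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {y!r}")
    S, I, V, G = y
    P = S + I
    mu = division_rate(t, params)
    phi_t = params.phi * adsorption_multiplier(t, forcing)
    infection = phi_t * S * V
    dS = mu * S - params.m_P * S * P - infection - params.psi * S * G
    dI = infection - params.m_P * I * P - params.eta * I - params.psi * I * G
    dV = params.beta * params.eta * I - phi_t * P * V - params.m_V * V * V
    dG = params.e_eff * params.psi * P * G + params.gamma * G - params.m_G * G * G
    return np.array([dS, dI, dV, dG])


def specialism_fraction(states, params: LifeHistoryParams) -> float:
    """Fraction of grazer growth attributable to *Prochlorococcus*.

    For each state the grazer's per-capita gain splits into a specialist
    part e_eff * psi * (S+I) and a generalist part gamma; the specialism
    fraction is the time average of the specialist share.  Equals 1 for a
    pure specialist (gamma = 0) and 0 when grazing on *Prochlorococcus*
    contributes nothing.

    ``states`` is a sequence of :class:`CommunityState` or an (n, 4) array.
    """
    arr = np.asarray(
        [s.to_array() if isinstance(s, CommunityState) else s for s in states],
        dtype=float,
    )
    if arr.size == 0:
        raise ValueError("empty trajectory")
    P = arr[:, 0] + arr[:, 1]
    specialist = params.e_eff * params.psi * P
    total = specialist + params.gamma
    ok = total > 0
    if not np.any(ok):
        raise ValueError("grazer growth sources are zero at every time point")
    return float(np.mean(specialist[ok] / total[ok]))
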