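"""Model state, life-history parameters and forcing configuration.

The community model tracks four populations in a well-mixed near-surface
water parcel: susceptible *Prochlorococcus* cells (S), virus-infected cells
(I), free cyanophage particles (V) and heterotrophic nanoflagellate grazers
(G), all in number per litre.  Division of *Prochlorococcus* is forced by
the diel light cycle; in a model variant the viral adsorption rate also
varies over the day as a step function.

Time is measured in days, with t = 0 anchored to 06:00 local time, so local
noon is t mod 1 = 0.25 and local midnight is t mod 1 = 0.75.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "LifeHistoryParams",
    "CommunityState",
    "ForcingConfig",
    "PARAM_NAMES",
    "GAMMA_VARIANTS",
    "load_config",
    "save_config",
]

#: Canonical parameter ordering used by the numerical engine and inference.
PARAM_NAMES = (
    "mu_ave",
    "delta_mu",
    "delta_t",
    "m_P",
    "m_V",
    "m_G",
    "phi",
    "psi",
    "beta",
    "eta",
    "e_eff",
    "gamma",
)

#: The grazer-generalism gradient studied: gamma = 0 is a pure specialist
#: (all grazer growth from *Prochlorococcus*); larger values grant the
#: grazer a net growth rate from other prey, in day^-1.
GAMMA_VARIANTS = (0.0, 0.01, 0.05, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class LifeHistoryParams:
    """Rate and trait parameters of the community model.

    Parameters
    ----------
    mu_ave : float
        Mean *Prochlorococcus* division rate, day^-1.
    delta_mu : float
        Fractional amplitude of the diel division oscillation, in [0, 1].
    delta_t : float
        Phase offset of the division oscillation, days, in [0, 1).
    m_P, m_V, m_G : float
        Quadratic (higher-order) loss coefficients for *Prochlorococcus*,
        viruses and grazers, in L cell^-1 day^-1, L virion^-1 day^-1 and
        L grazer^-1 day^-1.
    phi : float
        Viral adsorption rate, L day^-1.
    psi : float
        Grazer clearance rate, L day^-1.
    beta : float
        Burst size, virions released per lysed cell (>= 1).
    eta : float
        Lysis rate, day^-1 (reciprocal of the mean latent period).
    e_eff : float
        Effective gross growth efficiency of grazing on *Prochlorococcus*
        (GGE times the prey:grazer nitrogen-quota ratio), grazers cell^-1.
        The three underlying factors only enter the dynamics through this
        product, so they are represented by a single parameter.
    gamma : float
        Net grazer gain rate from non-*Prochlorococcus* prey, day^-1.
        gamma = 0 is a pure specialist.
    """

    mu_ave: float
    delta_mu: float
    delta_t: float
    m_P: float
    m_V: float
    m_G: float
    phi: float
    psi: float
    beta: float
    eta: float
    e_eff: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not 0.0 <= self.delta_mu <= 1.0:
            raise ValueError(
                f"delta_mu must lie in [0, 1] (division rate would go "
                f"negative), got {self.delta_mu!r}"
            )
        if not 0.0 <= self.delta_t < 1.0:
            raise ValueError(f"delta_t must lie in [0, 1), got {self.delta_t!r}")
        if self.beta < 1.0:
            raise ValueError(f"beta must be >= 1 virion/cell, got {self.beta!r}")

    def to_array(self) -> np.ndarray:
        """Parameter vector in the canonical :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "LifeHistoryParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "LifeHistoryParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **changes) -> "LifeHistoryParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CommunityState:
    """Population abundances (per litre): S, I, V, G."""

    S: float
    I: float
    V: float
    G: float

    def __post_init__(self) -> None:
        for name in ("S", "I", "V", "G"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")

    @property
    def pro(self) -> float:
        """Total *Prochlorococcus* abundance, S + I."""
        return self.S + self.I

    @property
    def infected_pct(self) -> float:
        """Percentage of *Prochlorococcus* cells infected; 0 if no cells."""
        p = self.pro
        return 100.0 * self.I / p if p > 0 else 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.V, self.G], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CommunityState":
        return cls(*map(float, values))


@dataclass(frozen=True)
class ForcingConfig:
    """Diel forcing switches.

    Division is always diel-forced (through ``delta_mu``); this config
    controls the optional step-function modulation of the adsorption rate:
    ``low_factor`` applies from local midnight to noon and ``high_factor``
    from noon to midnight.  With the defaults (0.5 / 1.5) the daily mean
    adsorption rate is preserved.

    ``clock_origin`` records the local clock time of t = 0; the model's
    phase conventions are tied to 06:00 and other origins are rejected.
    """

    diel_adsorption: bool = False
    low_factor: float = 0.5
    high_factor: float = 1.5
    clock_origin: str = "06:00"
    require_mean_preserving: bool = True

    def __post_init__(self) -> None:
        if self.low_factor < 0 or self.high_factor < 0:
            raise ValueError("adsorption factors must be >= 0")
        if self.clock_origin != "06:00":
            raise ValueError(
                "t = 0 is anchored to 06:00 local time; other clock origins "
                "are not supported"
            )
        if self.require_mean_preserving and not np.isclose(
            (self.low_factor + self.high_factor) / 2.0, 1.0, rtol=0, atol=1e-12
        ):
            raise ValueError(
                "mean-preserving diel adsorption requires "
                "(low_factor + high_factor)/2 == 1; pass "
                "require_mean_preserving=False to lift this constraint"
            )


def load_config(path) -> dict:
    """Read a YAML config file into a dict of plain types.

    Recognised top-level sections (all optional): ``params`` (keys exactly
    the :data:`PARAM_NAMES`), ``init`` (S, I, V, G), ``forcing`` (fields of
    :class:`ForcingConfig`) plus free-form sections used by the pipeline
    stages.  Helper constructors below turn sections into typed objects.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def params_from_config(cfg: dict) -> LifeHistoryParams:
    return LifeHistoryParams.from_dict(cfg["params"])


def state_from_config(cfg: dict) -> CommunityState:
    return CommunityState(**cfg["init"])


def forcing_from_config(cfg: dict) -> ForcingConfig:
    return ForcingConfig(**cfg.get("forcing", {}))
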