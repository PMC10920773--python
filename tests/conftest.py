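import numpy as np
import pytest

from eclip import (
    DEFAULT_INIT,
    DEFAULT_TRUE_PARAMS,
    CommunityState,
    ForcingConfig,
    GeneratorConfig,
    LifeHistoryParams,
    generate,
)


@pytest.fixture(scope="session")
def params() -> LifeHistoryParams:
    """The cruise-like default parameter set (stable coexistence)."""
    return DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def init() -> CommunityState:
    return DEFAULT_INIT


@pytest.fixture(scope="session")
def diel_forcing() -> ForcingConfig:
    return ForcingConfig(diel_adsorption=True)


@pytest.fixture(scope="session")
def generalist_params() -> LifeHistoryParams:
    """A coexisting very-generalist (gamma = 0.5) baseline.

    The grazer quadratic loss must rise with gamma for grazers not to
    overwhelm the prey — the same loss/gain trade-off the fitted variants
    show (short grazer residence times at high generalism).
    """
    return DEFAULT_TRUE_PARAMS.replace(gamma=0.5, m_G=5.5e-7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def observations_with_truth():
    """One low-noise synthetic cruise, shared across tests."""
    return generate(GeneratorConfig.low_noise(), seed=11)


def random_state(rng, scale=None) -> np.ndarray:
    """Random community state at field-like scales."""
    scale = scale or (1e8, 1e6, 1e9, 1e6)
    return np.array(scale) * rng.lognormal(0.0, 0.5, size=4)


def random_params(rng) -> LifeHistoryParams:
    """Random valid parameter set spanning the plausible decades."""
    return LifeHistoryParams(
        mu_ave=rng.uniform(0.1, 1.5),
        delta_mu=rng.uniform(0.0, 1.0),
        delta_t=rng.uniform(0.0, 1.0),
        m_P=10 ** rng.uniform(-12, -9),
        m_V=10 ** rng.uniform(-12, -9),
        m_G=10 ** rng.uniform(-10, -7),
        phi=10 ** rng.uniform(-13, -10),
        psi=10 ** rng.uniform(-9, -6),
        beta=rng.uniform(1.0, 500.0),
        eta=rng.uniform(0.5, 6.0),
        e_eff=10 ** rng.uniform(-5, -2),
        gamma=rng.choice([0.0, 0.01, 0.05, 0.1, 0.2, 0.5]),
    )
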