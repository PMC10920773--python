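"""Likelihood behaviour, posterior sampling contracts and variant comparison."""

import dataclasses

import numpy as np
import pytest

from eclip import (
    GeneratorConfig,
    LikelihoodEvaluator,
    MCMCOptions,
    NoiseSpec,
    Prior,
    PriorSpec,
    compare_variants,
    default_priors,
    generate,
    sample_posterior,
)
from eclip.observations import SIGNALS

TINY_MCMC = MCMCOptions(
    n_warmup=40, n_samples=40, n_walkers=48, seed=123, n_starts=2, map_maxfev=400
)

CLEAN = dict(
    noise_sigma={s: 0.0 for s in SIGNALS},
    trend_slopes={s: 0.0 for s in SIGNALS},
)


@pytest.fixture(scope="module")
def clean_obs_truth():
    return generate(GeneratorConfig(**CLEAN), seed=4)


@pytest.fixture(scope="module")
def tiny_fit(observations_with_truth):
    obs, _ = observations_with_truth
    return sample_posterior(obs, gamma=0.0, mcmc_opts=TINY_MCMC)


class TestLikelihood:
    def test_maximised_at_truth_along_scan(self, clean_obs_truth):
        """Noiseless data: a 1-D scan of the clearance rate peaks at the
        generating value (grid-scan oracle)."""
        obs, truth = clean_obs_truth
        ev = LikelihoodEvaluator(
            obs, noise=NoiseSpec(mode="marginal"), init=truth.init,
            infer_init=False,
        )
        scales = np.geomspace(0.5, 2.0, 11)
        ll = [
            ev.log_likelihood(truth.params.replace(psi=truth.params.psi * s))
            for s in scales
        ]
        assert np.argmax(ll) == 5  # the grid point at scale 1.0

    def test_doubling_sigma_lowers_attainable_loglik(self, clean_obs_truth):
        # at the maximum-attainable point (residuals ~ 0) the Gaussian
        # peak density falls when the scale doubles
        obs, truth = clean_obs_truth
        sig = {"pro": 2e6, "infected_pct": 0.1, "virus": 2e7, "grazer": 3e4}
        kw = dict(init=truth.init, infer_init=False)
        ev1 = LikelihoodEvaluator(obs, noise=NoiseSpec(mode="fixed", sigmas=sig), **kw)
        sig2 = {k: 2 * v for k, v in sig.items()}
        ev2 = LikelihoodEvaluator(obs, noise=NoiseSpec(mode="fixed", sigmas=sig2), **kw)
        ll1 = ev1.log_likelihood(truth.params)
        ll2 = ev2.log_likelihood(truth.params)
        assert np.isfinite(ll1) and ll2 < ll1

    def test_failed_simulation_is_minus_inf(self, observations_with_truth, params):
        obs, _ = observations_with_truth
        ev = LikelihoodEvaluator(obs, noise=NoiseSpec(mode="marginal"))
        runaway = params.replace(mu_ave=1.5, delta_mu=0.0, psi=0.0, phi=0.0,
                                 m_P=0.0, m_V=0.0, m_G=0.0, e_eff=0.0)
        assert ev.log_likelihood(runaway) == -np.inf

    def test_level_information_retained(self, clean_obs_truth):
        """The detrending keeps absolute magnitudes in the comparison: a
        model at twice the population scale must fit far worse even though
        its oscillation shape is unchanged."""
        obs, truth = clean_obs_truth
        ev = LikelihoodEvaluator(obs, noise=NoiseSpec(mode="marginal"),
                                 init=truth.init, infer_init=False)
        ll_truth = ev.log_likelihood(truth.params)
        shifted = dataclasses.replace(
            truth.init, S=truth.init.S * 2, I=truth.init.I * 2,
        )
        ll_shifted = ev.log_likelihood(truth.params, init_state=shifted)
        assert ll_truth - ll_shifted > 100


class TestPriors:
    def test_default_priors_cover_all_parameters(self):
        spec = default_priors(0.05)
        assert spec.fixed == {"gamma": 0.05}
        assert len(spec.free) == 11

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            Prior("log-uniform", -1.0, 2.0)
        with pytest.raises(ValueError):
            Prior("uniform", 3.0, 1.0)
        with pytest.raises(ValueError):
            Prior("truncated-normal", 0.0, 1.0)  # mu/sd missing
        with pytest.raises(ValueError, match="both free and fixed"):
            PriorSpec(
                free=default_priors().free,
                fixed={"mu_ave": 0.5, "gamma": 0.0},
            )

    def test_log_truncated_normal_density_integrates(self):
        from scipy.integrate import quad

        p = Prior("log-truncated-normal", 0.1, 1.5, mu=np.log(0.55), sd=0.18)
        zlo, zhi = p.z_bounds
        total, _ = quad(lambda z: np.exp(p.log_prob_z(z)), zlo, zhi)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestSamplePosterior:
    def test_same_seed_identical_chains(self, observations_with_truth):
        obs, _ = observations_with_truth
        a = sample_posterior(obs, gamma=0.0, mcmc_opts=TINY_MCMC)
        b = sample_posterior(obs, gamma=0.0, mcmc_opts=TINY_MCMC)
        assert np.array_equal(a.chains, b.chains)
        assert np.array_equal(a.log_prob, b.log_prob)

    def test_result_contract(self, tiny_fit):
        fit = tiny_fit
        assert set(fit.free_life_history) == {
            "mu_ave", "delta_mu", "delta_t", "m_P", "m_V", "m_G",
            "phi", "psi", "beta", "eta", "e_eff",
        }
        # noise scales and initial conditions are sampled alongside
        assert sum(n.startswith("sigma_") for n in fit.param_names) == 4
        assert sum(n.startswith("init_") for n in fit.param_names) == 4
        for name in fit.param_names:
            assert name in fit.rhat and name in fit.ess
            row = fit.summary.loc[name]
            assert row["q2.5"] <= row["median"] <= row["q97.5"]
        assert np.isfinite(fit.log_prob).all()
        assert np.isfinite(fit.log_lik).all()

    def test_prior_only_recovers_prior_quantiles(self, observations_with_truth):
        obs, _ = observations_with_truth
        fit = sample_posterior(
            obs, gamma=0.0, prior_only=True,
            mcmc_opts=MCMCOptions(n_warmup=200, n_samples=400, n_walkers=48,
                                  seed=77),
        )
        # uniform prior on the division phase: quantiles of U(0, 1)
        dt = fit.flat("delta_t")
        assert np.median(dt) == pytest.approx(0.5, abs=0.06)
        assert np.quantile(dt, 0.1) == pytest.approx(0.1, abs=0.06)
        # log-uniform prior on clearance: median at the geometric center
        psi = np.log10(fit.flat("psi"))
        assert np.median(psi) == pytest.approx(-7.0, abs=0.25)

    def test_draws_reconstruct_parameter_sets(self, tiny_fit):
        p = tiny_fit.draw_params(3)
        assert p.gamma == 0.0
        init = tiny_fit.draw_init(3)
        assert init.S > 0 and init.V > 0


class TestCompareVariants:
    def test_single_fit_single_row(self, tiny_fit):
        table = compare_variants([tiny_fit])
        assert len(table) == 1
        assert bool(table["within_margin"].iloc[0])

    def test_two_variants_aligned(self, observations_with_truth, tiny_fit):
        obs, _ = observations_with_truth
        other = sample_posterior(obs, gamma=0.5, mcmc_opts=TINY_MCMC)
        table = compare_variants([other, tiny_fit])
        assert list(table["gamma"]) == [0.0, 0.5]
        assert table["delta_best"].min() == 0.0
        assert np.isfinite(table["best_log_lik"]).all()

    def test_mixed_observation_sets_rejected(self, tiny_fit):
        other_obs, _ = generate(GeneratorConfig.low_noise(), seed=99)
        other = sample_posterior(other_obs, gamma=0.0, mcmc_opts=TINY_MCMC)
        with pytest.raises(ValueError, match="different observation sets"):
            compare_variants([tiny_fit, other])


class TestPartitionPosterior:
    def test_summary_table_and_closure(self, observations_with_truth, tiny_fit):
        from eclip import partition_posterior

        obs, _ = observations_with_truth
        table = partition_posterior(tiny_fit, obs, n_draws=40, seed=1)
        means = table["mean"]
        assert means[["f_lysis", "f_grazing", "f_other"]].sum() == pytest.approx(
            1.0, abs=1e-6
        )
        assert (table.loc["f_grazing", "q2.5"] <= table.loc["f_grazing", "median"]
                <= table.loc["f_grazing", "q97.5"])
        assert table.loc["grazer_residence", "median"] > 0

    def test_degenerate_posterior_zero_width(self, observations_with_truth, tiny_fit):
        from eclip import partition_posterior

        obs, _ = observations_with_truth
        frozen = dataclasses.replace(
            tiny_fit,
            chains=np.tile(tiny_fit.chains[:1, :1, :], (4, 5, 1)),
            log_prob=np.zeros((4, 5)),
            log_lik=np.zeros((4, 5)),
        )
        table = partition_posterior(frozen, obs, n_draws=10, seed=2)
        width = table["q97.5"] - table["q2.5"]
        assert np.allclose(width, 0.0, atol=1e-12)
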