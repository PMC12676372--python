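"""MCMC samplers: likelihood, chain accounting, degenerate cases, posteriors."""

import numpy as np
import pytest
from scipy.stats import norm

from qmrifit.core import BoundSpec, ValidationError
from qmrifit.mcmc import (
    ChainStore,
    McmcOptions,
    ensemble_sample,
    log_likelihood,
    mh_sample,
    retain,
    summarize,
)
from qmrifit.models import GaussianMeanModel
from qmrifit.synthdata import gen_gaussian_toy


class TestLogLikelihood:
    def test_zero_residual_is_zero(self):
        y = np.ones((2, 5))
        assert np.all(log_likelihood(y, y, 1.0) == 0.0)

    def test_unit_z_pair(self):
        s = 0.7
        y = np.array([[s, s]])
        assert log_likelihood(y, np.zeros((1, 2)), s)[0] == pytest.approx(-1.0)

    def test_doubling_sigma_quarters_value(self, rng):
        y = rng.standard_normal((3, 8))
        p = rng.standard_normal((3, 8))
        assert np.allclose(log_likelihood(y, p, 2.0), 0.25 * log_likelihood(y, p, 1.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            log_likelihood(np.ones((1, 2)), np.zeros((1, 2)), 0.0)


class TestRetain:
    def test_mh_table_settings_give_900(self):
        total, _ = retain(25000, 0.10, 100, 4)
        assert total == 900

    def test_ensemble_table_settings_give_900(self):
        total, _ = retain(2000, 0.10, 100, 50)
        assert total == 900

    def test_no_burnin_no_thinning_keeps_everything(self):
        total, idx = retain(500, 0.0, 1, 1)
        assert total == 500
        assert np.array_equal(idx, np.arange(500))

    def test_zero_retention_is_an_error(self):
        with pytest.raises(ValidationError, match="retained"):
            retain(10, 0.5, 100, 4)


def _toy_setup(n_voxels=5, n_obs=50, seed=9):
    toy = gen_gaussian_toy(n_obs=n_obs, theta_true=1.0, sigma=1.0, seed=seed, n_voxels=n_voxels)
    model = GaussianMeanModel(bounds=(-10.0, 10.0), n_obs=n_obs)
    return toy, model


class TestMetropolisHastings:
    def test_zero_step_size_chain_never_moves(self):
        toy, model = _toy_setup()
        opts = McmcOptions(iteration=200, burnin=0.0, thinning=10, n_proposals=2,
                           x_step_size={"theta": 0.0}, noise_sd=1.0, seed=1)
        ch = mh_sample(model, toy["y"], grid=toy["grid"], init={"theta": 0.5},
                       options=opts, layout="list")
        assert np.all(ch.samples == 0.5)

    def test_all_samples_inside_bounds_and_acceptance_in_unit_interval(self):
        toy, model = _toy_setup()
        opts = McmcOptions(iteration=500, burnin=0.1, thinning=5, n_proposals=2,
                           x_step_size={"theta": 0.5}, noise_sd=1.0, seed=2)
        ch = mh_sample(model, toy["y"], grid=toy["grid"], options=opts, layout="list")
        assert np.all((ch.samples > -10.0) & (ch.samples < 10.0))
        assert np.all((ch.acceptance_rate >= 0) & (ch.acceptance_rate <= 1))

    def test_retained_count_matches_accounting(self):
        toy, model = _toy_setup()
        opts = McmcOptions(iteration=1000, burnin=0.2, thinning=25, n_proposals=3,
                           x_step_size={"theta": 0.3}, noise_sd=1.0, seed=3)
        ch = mh_sample(model, toy["y"], grid=toy["grid"], options=opts, layout="list")
        total, _ = retain(1000, 0.2, 25, 3)
        assert ch.n_retained == total

    def test_stationary_frequencies_match_discretised_posterior(self):
        # two-state check: P(theta < cut) under the closed-form Gaussian posterior
        toy, model = _toy_setup(n_voxels=1, n_obs=100, seed=21)
        opts = McmcOptions(iteration=20000, burnin=0.1, thinning=5, n_proposals=4,
                           x_step_size={"theta": 0.25}, noise_sd=1.0, seed=4)
        ch = mh_sample(model, toy["y"], grid=toy["grid"], options=opts, layout="list")
        flat = ch.samples[0, :, :, 0].ravel()
        cut = toy["posterior_mean"][0] + 0.05
        p_emp = np.mean(flat < cut)
        p_true = norm.cdf(0.05 / toy["posterior_sd"])
        assert p_emp == pytest.approx(p_true, abs=0.03)


class TestEnsemble:
    def test_stretch_factor_support_and_cdf(self, rng):
        a = 2.0
        u = rng.random(200_000)
        z = ((a - 1.0) * u + 1.0) ** 2 / a
        assert z.min() >= 1 / a and z.max() <= a
        # analytic CDF of the 1/sqrt(z) density on [1/a, a]
        for t in (0.6, 1.0, 1.5):
            cdf = (np.sqrt(a * t) - 1) / (a - 1)
            assert np.mean(z <= t) == pytest.approx(cdf, abs=0.01)

    def test_walker_count_validation(self):
        with pytest.raises(ValidationError):
            McmcOptions(algorithm="ensemble", n_walkers=5)
        with pytest.raises(ValidationError):
            McmcOptions(algorithm="ensemble", n_walkers=2)

    def test_samples_respect_bounds(self):
        toy, model = _toy_setup()
        opts = McmcOptions(algorithm="ensemble", iteration=300, burnin=0.1, thinning=5,
                           n_walkers=10, noise_sd=1.0, seed=5)
        ch = ensemble_sample(model, toy["y"], grid=toy["grid"], options=opts, layout="list")
        assert np.all((ch.samples > -10.0) & (ch.samples < 10.0))

    def test_acceptance_factor_is_likelihood_ratio_for_one_parameter(self):
        # d = 1: z^(d-1) = 1, so a symmetric-likelihood proposal accepts at rate
        # indistinguishable from plain MH on the same target; sanity: acceptance
        # is within (0, 1) and the posterior mean is unbiased on the toy
        toy, model = _toy_setup(n_voxels=3, n_obs=100, seed=22)
        opts = McmcOptions(algorithm="ensemble", iteration=3000, burnin=0.2, thinning=10,
                           n_walkers=12, noise_sd=1.0, seed=6)
        ch = ensemble_sample(model, toy["y"], grid=toy["grid"], options=opts, layout="list")
        s = summarize(ch)
        assert np.allclose(s.mean["theta"], toy["posterior_mean"], atol=4 * toy["posterior_sd"])
        assert 0 < ch.acceptance_rate.mean() < 1


class TestSummarize:
    def _store(self, arr):
        arr = np.asarray(arr, dtype=float).reshape(1, 1, -1, 1)
        return ChainStore(arr, ("p",), np.arange(arr.shape[2]), np.ones((1, 1)))

    def test_identical_samples_zero_std(self):
        s = summarize(self._store([3.0, 3.0, 3.0]))
        assert s.mean["p"][0] == 3.0
        assert s.std["p"][0] == 0.0

    def test_two_point_mean_and_sd(self):
        s = summarize(self._store([0.0, 2.0]))
        assert s.mean["p"][0] == pytest.approx(1.0)
        assert s.std["p"][0] == pytest.approx(np.sqrt(2.0))

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValidationError):
            summarize(self._store([1.0]))

    def test_iqr_option(self, rng):
        arr = rng.standard_normal(1000)
        s = summarize(self._store(arr), with_iqr=True)
        q = np.percentile(arr, [25, 75])
        assert s.iqr["p"][0] == pytest.approx(q[1] - q[0])


class TestOptionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"thinning": 0},
            {"burnin": 1.0},
            {"burnin": -0.1},
            {"noise_sd": 0.0},
            {"algorithm": "nuts"},
            {"step_size": 1.0, "algorithm": "ensemble"},
        ],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            McmcOptions(**kwargs)
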