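import numpy as np
import pytest

from sgmkit.features import summary_vector
from sgmkit.forward import SGMParameters, network_response
from sgmkit.inference import (
    NPEConfig,
    PriorBox,
    make_simulator,
    point_estimate,
    sample_posterior,
    sample_prior,
    simulate_batch,
    train_npe,
    tsnpe_fit,
)
from sgmkit.diagnostics import shrinkage


class TestSamplePrior:
    def test_draws_within_bounds(self, prior):
        draws = sample_prior(prior, 500, seed=0)
        assert prior.contains(draws).all()

    def test_seed_reproducibility(self, prior):
        assert np.array_equal(sample_prior(prior, 50, seed=4), sample_prior(prior, 50, seed=4))

    def test_uniform_mean_of_alpha(self, prior):
        draws = sample_prior(prior, 10000, seed=1)
        lo, hi = prior.lower[2], prior.upper[2]
        se = (hi - lo) / np.sqrt(12 * 10000)
        assert abs(draws[:, 2].mean() - (lo + hi) / 2) < 3 * se

    def test_default_prior_is_the_physiological_box(self, prior):
        assert np.allclose(prior.lower, [0.001, 0.001, 0.01, 0.5, 1.0, 1.0, 0.01])
        assert np.allclose(prior.upper, [0.03, 0.03, 1.0, 15.0, 20.0, 20.0, 0.3])


class TestSimulateBatch:
    def test_noiseless_determinism(self, conn16, grid, midpoint):
        theta = midpoint.to_array()[None, :]
        a = simulate_batch(theta, conn16, grid, noise_sigma=None)
        b = simulate_batch(theta, conn16, grid, noise_sigma=None)
        assert np.array_equal(a.summaries, b.summaries)

    def test_zero_sigma_equals_noise_off(self, conn16, grid, midpoint):
        theta = midpoint.to_array()[None, :]
        a = simulate_batch(theta, conn16, grid, noise_sigma=0.0, seed=1)
        b = simulate_batch(theta, conn16, grid, noise_sigma=None, seed=2)
        assert np.allclose(a.summaries, b.summaries)

    def test_batch_of_100_completes_with_finite_summaries(self, conn16, grid, prior):
        thetas = sample_prior(prior, 100, seed=6)
        batch = simulate_batch(thetas, conn16, grid, noise_sigma=0.1, seed=7)
        assert len(batch.summaries) + batch.n_failed == 100
        assert batch.n_failed <= 10
        assert np.all(np.isfinite(batch.summaries))


class TestTrainNpe:
    def test_uninformative_summaries_leave_posterior_near_prior(self, prior):
        """When summaries carry no information about theta the conditional
        posterior must stay close to the uniform prior (near-zero shrinkage)."""
        rng = np.random.default_rng(0)
        thetas = sample_prior(prior, 3000, seed=1)
        noise = rng.normal(size=(3000, 5))
        trained = train_npe(prior, thetas, noise, seed=2)
        ps = sample_posterior(trained, noise[0], m=5000, seed=3)
        s = shrinkage(prior.variance, ps.draws.var(axis=0))
        assert np.all(np.abs(s) < 0.15)

    def test_recovery_pulls_posterior_toward_truth(self, trained_npe, conn16, grid, midpoint, prior):
        resp = network_response(conn16, midpoint, grid)
        obs = summary_vector(resp.global_psd, grid)
        ps = sample_posterior(trained_npe, obs, m=5000, seed=9)
        alpha_star = midpoint.alpha
        lo, hi = prior.lower[2], prior.upper[2]
        # inside the central half of the prior range ...
        assert lo + 0.25 * (hi - lo) < ps.point_mean[2] < hi - 0.25 * (hi - lo)
        # ... and closer to truth than an average prior draw is
        assert abs(ps.point_mean[2] - alpha_star) < (hi - lo) / 4

    def test_training_reproducible_under_seed(self, prior, conn16, grid):
        thetas = sample_prior(prior, 600, seed=11)
        batch = simulate_batch(thetas, conn16, grid, noise_sigma=0.05, seed=12)
        t1 = train_npe(prior, batch.thetas, batch.summaries, seed=5)
        t2 = train_npe(prior, batch.thetas, batch.summaries, seed=5)
        obs = batch.summaries[0]
        d1 = sample_posterior(t1, obs, m=1000, seed=6).draws
        d2 = sample_posterior(t2, obs, m=1000, seed=6).draws
        assert np.array_equal(d1, d2)

    def test_requires_500_pairs(self, prior):
        thetas = sample_prior(prior, 100, seed=0)
        with pytest.raises(ValueError, match="500"):
            train_npe(prior, thetas, np.zeros((100, 4)))

    def test_layout_mismatch_rejected(self, trained_npe, grid):
        from sgmkit.features import SummaryVector, AperiodicFit

        bad = SummaryVector(
            aperiodic=AperiodicFit(0.0, 1.0, (1, 40)),
            first_peak=None,
            binned_psd=np.zeros(16),
            layout_version="other-layout/v9",
        )
        with pytest.raises(ValueError, match="layout"):
            sample_posterior(trained_npe, bad, m=1000)


class TestSamplePosterior:
    def test_draws_stay_inside_prior_box(self, trained_npe, conn16, grid, midpoint, prior):
        resp = network_response(conn16, midpoint, grid)
        obs = summary_vector(resp.global_psd, grid)
        ps = sample_posterior(trained_npe, obs, m=3000, seed=1)
        assert prior.contains(ps.draws).all()
        assert 0 < ps.acceptance_rate <= 1

    def test_same_seed_same_draws(self, trained_npe, conn16, grid, midpoint):
        resp = network_response(conn16, midpoint, grid)
        obs = summary_vector(resp.global_psd, grid)
        a = sample_posterior(trained_npe, obs, m=500, seed=3).draws
        b = sample_posterior(trained_npe, obs, m=500, seed=3).draws
        assert np.array_equal(a, b)

    def test_default_sample_count_is_10000(self, trained_npe, conn16, grid, midpoint):
        resp = network_response(conn16, midpoint, grid)
        obs = summary_vector(resp.global_psd, grid)
        ps = sample_posterior(trained_npe, obs, seed=2)
        assert len(ps.draws) == 10000


class TestPosteriorQuality:
    def test_informative_posterior_distinguishable_from_prior(self, trained_npe, conn16, grid, midpoint, prior):
        """After inference on a noiseless synthetic observation the posterior
        must be detectably narrower than the prior (classifier accuracy > 0.6)."""
        from sgmkit.diagnostics import c2st

        resp = network_response(conn16, midpoint, grid)
        obs = summary_vector(resp.global_psd, grid)
        ps = sample_posterior(trained_npe, obs, m=3000, seed=4)
        prior_draws = sample_prior(prior, 3000, seed=55)
        assert c2st(ps.draws, prior_draws, seed=0).accuracy > 0.6

    def test_central_interval_coverage_for_alpha(self, trained_npe, conn16, grid, prior):
        """The central 90% posterior interval for the long-range coupling
        covers the generating value in at least 70% of 20 synthetic
        observations (a loose calibration bound at desk-scale budgets)."""
        hits = 0
        for i in range(20):
            theta = sample_prior(prior, 1, seed=700 + i)[0]
            resp = network_response(conn16, SGMParameters.from_array(theta), grid)
            obs = summary_vector(resp.global_psd, grid)
            draws = sample_posterior(trained_npe, obs, m=2000, seed=800 + i).draws[:, 2]
            lo, hi = np.quantile(draws, [0.05, 0.95])
            hits += lo <= theta[2] <= hi
        assert hits >= 14


class TestPointEstimate:
    def _samples(self, draws, prior):
        from sgmkit.inference import PosteriorSamples

        return PosteriorSamples(
            draws=draws,
            observation_id="t",
            point_mean=draws.mean(axis=0),
            point_mode=np.zeros(7),
            acceptance_rate=1.0,
            prior=prior,
        )

    def test_constant_samples_give_both_estimates_equal(self, prior):
        c = prior.lower + 0.3 * prior.width
        draws = np.tile(c, (500, 1))
        s = self._samples(draws, prior)
        assert np.allclose(point_estimate(s, "mean"), c)
        assert np.allclose(point_estimate(s, "mode"), c)

    def test_symmetric_samples_mean_close_to_mode(self, prior):
        rng = np.random.default_rng(0)
        center = prior.lower + 0.5 * prior.width
        draws = rng.normal(center, 0.05 * prior.width, size=(20000, 7))
        draws = np.clip(draws, prior.lower, prior.upper)
        s = self._samples(draws, prior)
        grid_step = prior.width / 511
        assert np.all(np.abs(point_estimate(s, "mean") - point_estimate(s, "mode")) < 5 * grid_step)

    def test_right_skewed_samples_have_mean_above_mode(self, prior):
        rng = np.random.default_rng(1)
        raw = rng.exponential(0.15, size=(20000, 7))  # mode at 0, long right tail
        draws = prior.lower + np.clip(raw, 0, 1) * prior.width
        s = self._samples(draws, prior)
        assert np.all(point_estimate(s, "mean") > point_estimate(s, "mode"))

    def test_too_few_draws_rejected(self, prior):
        s = self._samples(np.tile(prior.lower + 0.5 * prior.width, (50, 1)), prior)
        with pytest.raises(ValueError, match="100"):
            point_estimate(s)


@pytest.fixture(scope="module")
def tsnpe_run(conn16, grid, prior):
    sim = make_simulator(conn16, grid, noise_sigma=0.1)
    theta_star = sample_prior(prior, 1, seed=77)[0]
    resp = network_response(conn16, SGMParameters.from_array(theta_star), grid)
    obs = summary_vector(resp.global_psd, grid)
    trained = tsnpe_fit(prior, sim, obs, rounds=2, budget_per_round=600, seed=0)
    return trained, obs, theta_star


class TestTsnpe:
    def test_zero_leakage_outside_prior(self, tsnpe_run, prior):
        trained, obs, _ = tsnpe_run
        ps = sample_posterior(trained, obs, m=5000, seed=1)
        assert prior.contains(ps.draws).all()
        assert ps.acceptance_rate == 1.0

    def test_truncation_box_contained_in_prior(self, tsnpe_run, prior):
        trained, _, _ = tsnpe_run
        lo, hi = trained.truncation_box
        assert np.all(lo >= prior.lower)
        assert np.all(hi <= prior.upper)
        assert np.all(lo < hi)

    def test_round_count_warning(self, conn16, grid, prior):
        sim = make_simulator(conn16, grid, noise_sigma=0.1)
        obs_batch = sim(sample_prior(prior, 1, seed=5), 6)
        with pytest.warns(UserWarning, match="rounds"):
            tsnpe_fit(prior, sim, obs_batch.summaries[0], rounds=1, budget_per_round=600, seed=2)
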