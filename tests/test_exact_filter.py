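import math

import numpy as np
import pytest

from censorfilter.exact_filter import (
    GridPosterior,
    gaussian_grid_posterior,
    hpd_region,
    make_grid,
    posterior_moments,
    posterior_skewness,
    predict,
    run_filter,
    update,
)
from censorfilter.model import ModelParameters, TrialObservation, trial_log_likelihood
from censorfilter.simulator import simulate_realization

from oracles import kalman_log_rt


class TestMakeGrid:
    def test_reference_range(self, params):
        g = make_grid(params, m_sd=8.0, n_points=1001)
        assert g[0] == pytest.approx(-1.5, abs=0.01)
        assert g[-1] == pytest.approx(2.5, abs=0.01)
        assert len(g) == 1001

    def test_three_points(self, params):
        g = make_grid(params, n_points=3)
        assert len(g) == 3
        assert g[1] == pytest.approx((g[0] + g[2]) / 2)

    def test_uniform_spacing(self, params):
        g = make_grid(params, n_points=101)
        np.testing.assert_allclose(np.diff(g), (g[-1] - g[0]) / 100)

    def test_nonstationary_requires_bounds(self):
        p = ModelParameters(a1=1.0)
        with pytest.raises(ValueError, match="bounds"):
            make_grid(p)
        g = make_grid(p, bounds=(-5, 5), n_points=11)
        assert len(g) == 11


class TestPredict:
    def test_point_mass_at_steady_state(self, params, grid, kernel):
        mass = np.zeros_like(grid)
        mass[np.argmin(np.abs(grid - 0.5))] = 1.0
        belief = GridPosterior(grid=grid, mass=mass)
        pred = predict(belief, params, kernel=kernel)
        mean, var = posterior_moments(pred)
        assert mean == pytest.approx(0.5, abs=1e-3)
        assert var == pytest.approx(params.sigma_eps**2, rel=1e-2)

    def test_near_deterministic_map_shifts_prior(self, grid):
        # tiny process noise: prediction is approximately the affinely
        # mapped copy of the prior
        p = ModelParameters(a1=0.95, a0=0.025, sigma_eps=0.02)
        prior = gaussian_grid_posterior(grid, 0.9, 0.1)
        pred = predict(prior, p)
        mean, var = posterior_moments(pred)
        assert mean == pytest.approx(p.a1 * 0.9 + p.a0, abs=1e-6)
        assert var == pytest.approx(p.a1**2 * 0.01 + p.sigma_eps**2, rel=1e-4)

    def test_moments_match_closed_form(self, params, grid, kernel):
        prior = gaussian_grid_posterior(grid, 0.3, math.sqrt(0.04))
        pred = predict(prior, params, kernel=kernel)
        mean, var = posterior_moments(pred)
        assert mean == pytest.approx(params.a1 * 0.3 + params.a0, abs=1e-4)
        assert var == pytest.approx(
            params.a1**2 * 0.04 + params.sigma_eps**2, abs=1e-4
        )

    def test_normalized_after_predict(self, params, stationary_prior, kernel):
        pred = predict(stationary_prior, params, kernel=kernel)
        assert pred.mass.sum() == pytest.approx(1.0, abs=1e-10)


class TestUpdate:
    def test_deletion_identity_on_censored(self, params, stationary_prior):
        obs = TrialObservation(index=1, threshold=0.9, status="censored")
        post = update(stationary_prior, obs, params, scheme="deletion")
        np.testing.assert_array_equal(post.mass, stationary_prior.mass)

    def test_flat_prior_recovers_likelihood(self, params, grid):
        flat = GridPosterior(grid=grid, mass=np.full(grid.size, 1.0 / grid.size))
        obs = TrialObservation(index=1, threshold=0.9, status="observed", rt=0.6)
        post = update(flat, obs, params)
        lik = np.exp(trial_log_likelihood(obs, grid, params))
        np.testing.assert_allclose(post.mass, lik / lik.sum(), rtol=1e-10)

    def test_censored_full_update_raises_mean(self, params, stationary_prior):
        # b1 > 0: a censored trial is evidence the state is high
        obs = TrialObservation(index=1, threshold=0.9, status="censored")
        post = update(stationary_prior, obs, params, scheme="full")
        assert posterior_moments(post)[0] > posterior_moments(stationary_prior)[0]

    def test_censored_variance_between_full_observation_and_prediction(
        self, params, stationary_prior
    ):
        # a censored trial carries less information than an observed RT,
        # more than no observation at all
        _, var_pred = posterior_moments(stationary_prior)
        cens = TrialObservation(index=1, threshold=0.9, status="censored")
        var_cens = posterior_moments(update(stationary_prior, cens, params))[1]
        seen = TrialObservation(index=1, threshold=0.9, status="observed", rt=0.85)
        var_obs = posterior_moments(update(stationary_prior, seen, params))[1]
        assert var_obs < var_cens <= var_pred + 1e-12

    def test_normalized_after_update(self, params, stationary_prior):
        obs = TrialObservation(index=1, threshold=0.9, status="observed", rt=0.3,
                               decision=1)
        post = update(stationary_prior, obs, params)
        assert post.mass.sum() == pytest.approx(1.0, abs=1e-10)


class TestRunFilter:
    def test_empty_input(self, params, stationary_prior):
        preds, posts = run_filter([], params, prior=stationary_prior)
        assert preds == [] and posts == []

    def test_prefix_then_resume_matches_full_run(self, params, stationary_prior,
                                                 kernel):
        sim = simulate_realization(params, 30, 0.9, seed=7)
        _, full = run_filter(sim.trials, params, prior=stationary_prior,
                             kernel=kernel)
        _, head = run_filter(sim.trials[:12], params, prior=stationary_prior,
                             kernel=kernel)
        _, tail = run_filter(sim.trials[12:], params, prior=head[-1],
                             kernel=kernel)
        np.testing.assert_allclose(full[-1].mass, tail[-1].mass, atol=1e-13)

    def test_matches_kalman_without_censoring(self, params):
        # grid filter == closed-form Kalman filter on uncensored log-RT data
        sim = simulate_realization(params, 100, 50.0, seed=3, with_decision=False)
        assert all(t.observed for t in sim.trials)
        grid = make_grid(params, n_points=2001)
        from censorfilter.model import steady_state_moments

        mean0, sd0 = steady_state_moments(params)
        prior = gaussian_grid_posterior(grid, mean0, sd0)
        _, posts = run_filter(sim.trials, params, prior=prior,
                              include_decision=False)
        km, kv = kalman_log_rt(sim.trials, params, mean0, sd0**2)
        gm = np.array([posterior_moments(p)[0] for p in posts])
        gv = np.array([posterior_moments(p)[1] for p in posts])
        np.testing.assert_allclose(gm, km, atol=1e-4)
        np.testing.assert_allclose(gv, kv, atol=1e-4)

    def test_grid_convergence(self, params):
        # doubling the resolution barely moves the posterior means
        sim = simulate_realization(params, 40, 0.9, seed=11)
        means = {}
        for n in (1001, 2001):
            grid = make_grid(params, n_points=n)
            _, posts = run_filter(sim.trials, params, grid=grid)
            means[n] = np.array([posterior_moments(p)[0] for p in posts])
        np.testing.assert_allclose(means[1001], means[2001], atol=1e-4)

    def test_skew_grows_positive_during_censored_run(self, params,
                                                     stationary_prior):
        # with b1 > 0 a run of censored trials skews the posterior right
        trials = [
            TrialObservation(index=k, threshold=0.9, status="censored")
            for k in range(1, 9)
        ]
        _, posts = run_filter(trials, params, prior=stationary_prior)
        assert posterior_skewness(posts[-1]) > 0


class TestPosteriorMoments:
    def test_symmetric_two_point_mass(self):
        grid = np.array([0.0, 0.5, 1.0])
        belief = GridPosterior(grid=grid, mass=np.array([0.5, 0.0, 0.5]))
        mean, var = posterior_moments(belief)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.25)

    def test_point_mass_has_zero_variance(self, grid):
        mass = np.zeros_like(grid)
        mass[123] = 1.0
        assert posterior_moments(GridPosterior(grid=grid, mass=mass))[1] == 0.0

    def test_recovers_gaussian_moments(self, grid):
        belief = gaussian_grid_posterior(grid, 0.5, 0.25)
        mean, var = posterior_moments(belief)
        assert mean == pytest.approx(0.5, abs=1e-6)
        assert var == pytest.approx(0.0625, abs=1e-6)


class TestHPDRegion:
    def test_uniform_belief(self, grid):
        flat = GridPosterior(grid=grid, mass=np.full(grid.size, 1.0 / grid.size))
        region = hpd_region(flat, 0.95)
        assert region.cells.size >= 0.95 * grid.size
        assert region.attained_mass >= 0.95

    def test_gaussian_matches_normal_quantiles(self, grid):
        belief = gaussian_grid_posterior(grid, 0.5, 0.25)
        region = hpd_region(belief, 0.95)
        (lo, hi), = region.intervals(belief)
        assert lo == pytest.approx(0.5 - 1.96 * 0.25, abs=0.01)
        assert hi == pytest.approx(0.5 + 1.96 * 0.25, abs=0.01)

    def test_bimodal_belief_gives_disjoint_intervals(self, grid):
        m1 = np.exp(-0.5 * ((grid - (-0.5)) / 0.1) ** 2)
        m2 = np.exp(-0.5 * ((grid - 1.5) / 0.1) ** 2)
        belief = GridPosterior(grid=grid, mass=(m1 + m2) / (m1 + m2).sum())
        region = hpd_region(belief, 0.95)
        assert len(region.intervals(belief)) == 2
        assert region.attained_mass >= 0.95

    def test_matches_brute_force_density_cutoff(self, grid):
        belief = gaussian_grid_posterior(grid, 0.2, 0.3)
        region = hpd_region(belief, 0.9)
        # brute force: scan candidate cutoffs over every distinct density
        w = belief.mass
        best_cells = None
        for cut in np.sort(np.unique(w))[::-1]:
            cells = np.flatnonzero(w >= cut)
            if w[cells].sum() >= 0.9:
                best_cells = cells
                break
        np.testing.assert_array_equal(region.cells, best_cells)

    def test_level_validated(self, stationary_prior):
        with pytest.raises(ValueError):
            hpd_region(stationary_prior, 1.0)
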