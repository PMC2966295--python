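import numpy as np
import pytest
from scipy import stats

from survmoe.weibull_posterior import (DegeneratePosteriorError, ShapeGrid,
                                       SufficientSummary, WeibullPrior,
                                       _eta_mode, sample_eta_laplace,
                                       sample_scale_given_shape,
                                       sample_shape_discretized,
                                       shape_marginal_logdensity)

from helpers import eta_conditional_logpdf, slice_sample_1d, \
    weibull_joint_logpdf


class TestScaleConditional:
    def test_prior_reproduced_without_data(self, rng):
        prior = WeibullPrior(a=3.0, b=2.0)
        draws = np.array([
            sample_scale_given_shape(SufficientSummary.empty(), 1.0, prior,
                                     rng) for _ in range(20000)])
        # alpha = 1 so lam = v ~ InvGamma(3, 2), mean 2/(3-1) = 1
        assert draws.mean() == pytest.approx(1.0, rel=0.05)

    def test_single_event_conjugate_update(self, rng):
        # one event t=1, eta=0, alpha=1, a=b=1: v ~ InvGamma(2, 2), E[v]=2
        summary = SufficientSummary(np.array([1.0]), np.array([1.0]))
        draws = np.array([
            sample_scale_given_shape(summary, 1.0, WeibullPrior(), rng)
            for _ in range(20000)])
        assert draws.mean() == pytest.approx(2.0, rel=0.05)

    def test_draws_match_unnormalized_conditional_density(self, rng):
        """Histogram of v = lam^alpha draws vs the likelihood-times-prior
        density computed by direct numeric normalization (chi-square GOF)."""
        t = np.array([0.8, 1.6, 2.3, 0.5, 1.1])
        delta = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        eta = np.array([0.2, -0.1, 0.0, 0.4, -0.3])
        summary = SufficientSummary(t, delta, eta)
        prior = WeibullPrior(a=1.5, b=0.8, c=1.0, d=1.0)
        alpha = 1.3
        draws = np.array([
            sample_scale_given_shape(summary, alpha, prior, rng) ** alpha
            for _ in range(20000)])

        grid = np.geomspace(draws.min() * 0.5, draws.max() * 2.0, 4000)
        logd = np.array([weibull_joint_logpdf(alpha, v, t, delta, eta, prior)
                         for v in grid])
        dens = np.exp(logd - logd.max())
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        edges = np.interp(np.linspace(0, 1, 21), cdf, grid)
        counts, _ = np.histogram(draws, bins=edges)
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01


class TestShapeMarginal:
    def test_prior_only_limit_is_flat(self):
        # no data, c=1, d=1: only the constant -a log b survives
        prior = WeibullPrior(a=2.0, b=3.0, c=1.0, d=1.0)
        grid = np.linspace(0.2, 8.0, 50)
        vals = shape_marginal_logdensity(grid, SufficientSummary.empty(),
                                         prior)
        np.testing.assert_allclose(vals, -2.0 * np.log(3.0), atol=1e-12)

    def test_matches_two_dimensional_quadrature(self):
        """Integrating the analytic alpha-marginal must equal integrating
        the (alpha, v) joint over both variables (2-event toy data)."""
        t = np.array([1.2, 0.7])
        delta = np.array([1.0, 1.0])
        eta = np.array([0.3, -0.2])
        summary = SufficientSummary(t, delta, eta)
        prior = WeibullPrior(a=2.0, b=1.5, c=1.2, d=0.8)
        alphas = np.linspace(0.1, 12.0, 300)
        vs = np.geomspace(1e-5, 1e4, 500)
        joint = np.array([[weibull_joint_logpdf(a, v, t, delta, eta, prior)
                           for v in vs] for a in alphas])
        inner = np.trapezoid(np.exp(joint - joint.max()), vs, axis=1)
        marg_2d = inner / inner.max()

        ld = shape_marginal_logdensity(alphas, summary, prior)
        marg_1d = np.exp(ld - ld.max())
        # same alpha-profile up to one global constant
        np.testing.assert_allclose(marg_2d / np.trapezoid(marg_2d, alphas),
                                   marg_1d / np.trapezoid(marg_1d, alphas),
                                   atol=5e-4)

    def test_censored_only_data_drops_event_terms(self):
        t = np.array([1.5, 2.5, 0.9])
        summary = SufficientSummary(t, np.zeros(3))
        prior = WeibullPrior(a=1.3, b=0.7, c=2.0, d=0.6)
        alphas = np.linspace(0.2, 5.0, 40)
        expected = ((prior.c - 1.0) * np.log(alphas)
                    + alphas * np.log(prior.d)
                    - prior.a * np.log(prior.b + summary.weighted_sum(alphas)))
        np.testing.assert_allclose(
            shape_marginal_logdensity(alphas, summary, prior), expected,
            atol=1e-12)

    def test_mode_near_generating_shape(self, rng):
        from survmoe.weibull import WeibullParams, sample_survival_time
        t = sample_survival_time(WeibullParams(5.0, 2.0), np.zeros(500), rng)
        summary = SufficientSummary(t, np.ones(500))
        grid = np.geomspace(0.5, 20.0, 2000)
        ld = shape_marginal_logdensity(grid, summary, WeibullPrior())
        assert grid[np.argmax(ld)] == pytest.approx(5.0, rel=0.15)


class TestShapeSampler:
    def test_frequencies_match_grid_probabilities(self, rng):
        t = np.array([0.9, 1.4, 2.0])
        summary = SufficientSummary(t, np.ones(3))
        prior = WeibullPrior()
        grid = ShapeGrid(lo=0.2, hi=8.0, size=25, jitter=False)
        draws = np.array([sample_shape_discretized(summary, prior, grid, rng)
                          for _ in range(20000)])
        logd = shape_marginal_logdensity(grid.points, summary, prior) \
            + grid.log_widths
        probs = np.exp(logd - logd.max())
        probs /= probs.sum()
        counts = np.array([(draws == p).sum() for p in grid.points])
        mask = probs * draws.size > 5
        res = stats.chisquare(counts[mask],
                              probs[mask] / probs[mask].sum() * counts[mask].sum())
        assert res.pvalue > 0.01

    def test_grid_refinement_stability(self):
        t = np.array([0.8, 1.1, 1.9, 2.4, 0.6])
        summary = SufficientSummary(t, np.ones(5))
        prior = WeibullPrior()
        means = []
        for size in (500, 5000):
            grid = ShapeGrid(lo=0.05, hi=30.0, size=size)
            logd = shape_marginal_logdensity(grid.points, summary, prior) \
                + grid.log_widths
            probs = np.exp(logd - logd.max())
            probs /= probs.sum()
            means.append(float(probs @ grid.points))
        assert means[1] == pytest.approx(means[0], rel=0.01)

    def test_degenerate_grid_raises(self, rng):
        # an overflowing weighted sum drives every grid density to -inf
        summary = SufficientSummary(np.array([2.0]), np.array([1.0]),
                                    np.array([1e4]))
        with pytest.raises(DegeneratePosteriorError):
            sample_shape_discretized(summary, WeibullPrior(),
                                     ShapeGrid(size=50), rng)


class TestEtaLaplace:
    def test_prior_reproduced_when_likelihood_vanishes(self, rng):
        draws = sample_eta_laplace(np.zeros(100_000), np.zeros(100_000),
                                   np.full(100_000, 0.7), 1.3, rng)
        assert draws.mean() == pytest.approx(0.7, abs=0.02)
        assert draws.var() == pytest.approx(1.3, rel=0.02)

    def test_mode_equation_closed_form(self):
        # delta=1, Lam=1, mean=0, sigma2=1: mode solves 1 - e^m - m = 0 at 0
        mode = _eta_mode(np.array([1.0]), np.array([1.0]), np.array([0.0]),
                         1.0)
        assert mode[0] == pytest.approx(0.0, abs=1e-9)

    def test_laplace_variance_at_mode(self, rng):
        draws = sample_eta_laplace(np.ones(200_000), np.ones(200_000),
                                   np.zeros(200_000), 1.0, rng)
        assert draws.var() == pytest.approx(0.5, rel=0.02)

    def test_matches_exact_conditional_when_prior_dominates(self, rng):
        """With a tight link prior the conditional is nearly Gaussian and
        the Laplace draw must match a slice-sampling run on the exact
        density."""
        delta, lam_h, mean, sigma2 = 1.0, 2.0, 1.0, 0.05
        draws = sample_eta_laplace(np.full(50_000, delta),
                                   np.full(50_000, lam_h),
                                   np.full(50_000, mean), sigma2, rng)
        exact = slice_sample_1d(
            lambda e: eta_conditional_logpdf(e, delta, lam_h, mean, sigma2),
            mean, 30_000, np.random.default_rng(5), width=0.5)
        assert draws.mean() == pytest.approx(exact.mean(), abs=0.01)

    def test_mode_finder_handles_extreme_inputs(self):
        delta = np.array([1.0, 0.0, 1.0, 0.0])
        lam_h = np.array([1e8, 1e-12, 1e-9, 50.0])
        mean = np.array([25.0, -30.0, 10.0, 4.0])
        sigma2 = 0.5
        mode = _eta_mode(delta, lam_h, mean, sigma2)
        g = delta - lam_h * np.exp(mode) - (mode - mean) / sigma2
        np.testing.assert_allclose(g, 0.0, atol=1e-5)

    def test_split_sampler_targets_joint(self, rng):
        """Alternating scale-given-shape and discretized-shape draws must
        target the same joint as direct 2-D grid evaluation (the split
        that fixes the slow-mixing shape/scale correlation)."""
        t = np.array([0.9, 1.7, 1.2])
        delta = np.array([1.0, 1.0, 0.0])
        eta = np.zeros(3)
        summary = SufficientSummary(t, delta, eta)
        prior = WeibullPrior()
        grid = ShapeGrid(lo=0.1, hi=10.0, size=400)

        alpha_draws = np.empty(20000)
        for i in range(alpha_draws.size):
            alpha_draws[i] = sample_shape_discretized(summary, prior, grid,
                                                      rng)

        alphas = np.linspace(0.1, 10.0, 400)
        vs = np.geomspace(1e-4, 1e4, 400)
        joint = np.array([[weibull_joint_logpdf(a, v, t, delta, eta, prior)
                           for v in vs] for a in alphas])
        marg = np.trapezoid(np.exp(joint - joint.max()), vs, axis=1)
        marg /= np.trapezoid(marg, alphas)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (marg[1:] + marg[:-1]) * np.diff(alphas))])
        for q in (0.25, 0.5, 0.75):
            grid_q = np.interp(q, cdf / cdf[-1], alphas)
            emp_q = np.quantile(alpha_draws, q)
            assert emp_q == pytest.approx(grid_q, rel=0.05)
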