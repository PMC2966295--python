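"""Independent oracles shared by the unit and acceptance tests.

Everything here deliberately avoids the package's own sampling code
paths: quadrature, slice sampling and exhaustive enumeration are used to
cross-check the conjugate algebra and the Gibbs kernels.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats


def slice_sample_1d(logpdf, x0: float, n_draws: int, rng, width: float = 2.0,
                    burn: int = 200, thin: int = 1) -> np.ndarray:
    """Univariate slice sampler with stepping-out, for log-concave targets."""
    draws = np.empty(n_draws)
    x = float(x0)
    total = burn + n_draws * thin
    kept = 0
    for i in range(total):
        logy = logpdf(x) + math.log(rng.random())
        lo, hi = x - width * rng.random(), 0.0
        hi = lo + width
        while logpdf(lo) > logy:
            lo -= width
        while logpdf(hi) > logy:
            hi += width
        while True:
            prop = rng.uniform(lo, hi)
            if logpdf(prop) > logy:
                x = prop
                break
            if prop < x:
                lo = prop
            else:
                hi = prop
        if i >= burn and (i - burn) % thin == 0:
            draws[kept] = x
            kept += 1
    return draws[:kept]


def eta_conditional_logpdf(eta, delta, lam_h, mean, sigma2):
    """Exact unnormalized log full conditional of the linear predictor."""
    return delta * eta - lam_h * np.exp(eta) - (eta - mean) ** 2 / (2 * sigma2)


def group_laplacian_marginal(beta_norm2: float, p: int, sigma2: float,
                             rho2: float) -> float:
    """Quadrature of the Normal x Gamma scale mixture over lambda.

    Integrates N_p(beta; 0, sigma^2 lambda I) Gamma(lambda; (p+1)/2,
    rate rho^2/2) dlambda; the result should be proportional to
    exp(-sqrt(rho2/sigma2) * ||beta||) (a multivariate Laplacian).
    """
    def integrand(lam):
        logp = (-0.5 * p * np.log(2 * np.pi * sigma2 * lam)
                - beta_norm2 / (2 * sigma2 * lam)
                + stats.gamma.logpdf(lam, a=(p + 1) / 2, scale=2.0 / rho2))
        return np.exp(logp)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def weibull_joint_logpdf(alpha, v, t, delta, eta, prior):
    """Log joint of (alpha, v = lam^alpha) and the data, prior included.

    Likelihood terms evaluated directly from the censored Weibull density
    with hazard multiplier exp(eta); prior alpha^(c-1) d^alpha
    InvGamma(v; a, b).
    """
    lam = v ** (1.0 / alpha)
    log_lam = np.log(lam)
    ll = 0.0
    for ti, di, ei in zip(t, delta, eta):
        z = alpha * (np.log(ti) - log_lam) + ei
        big_h = np.exp(z)
        if di:
            ll += np.log(alpha) - np.log(ti) + z
        ll -= big_h
    prior_ld = ((prior.c - 1.0) * np.log(alpha) + alpha * np.log(prior.d)
                + stats.invgamma.logpdf(v, a=prior.a, scale=prior.b))
    return ll + prior_ld


def normal_invchi2_marginal(x_members, m0, k0, v0, s0sq,
                            n_var: int = 4000) -> float:
    """Marginal likelihood of one covariate dimension under the
    Normal-Inv-chi^2 prior var ~ Inv-chi^2(v0, s0sq), mu | var ~ N(m0, var/k0).

    The mean is integrated out by elementary Gaussian algebra
    (completing the square); the variance by numeric quadrature on a wide
    log-spaced grid.
    """
    x = np.asarray(x_members, dtype=float)
    n = x.size
    if n == 0:
        return 1.0
    xbar = x.mean()
    ss = ((x - xbar) ** 2).sum()
    kn = k0 + n
    quad_term = ss + n * k0 / kn * (xbar - m0) ** 2
    var = np.geomspace(s0sq * 1e-8, s0sq * 1e8, n_var)
    log_mx = (-0.5 * n * np.log(2 * np.pi * var)
              + 0.5 * (np.log(k0) - np.log(kn))
              - quad_term / (2 * var))
    log_pv = stats.invgamma.logpdf(var, a=v0 / 2.0, scale=v0 * s0sq / 2.0)
    vals = np.exp(log_mx + log_pv)
    return float(np.trapezoid(vals, var))


def weibull_cluster_marginal(t, delta, prior, alpha_lo, alpha_hi,
                             n_alpha=400, n_v=600) -> float:
    """2-D grid marginal likelihood of a cluster's survival records.

    Direct numerical integration of the censored Weibull likelihood times
    the (alpha, v) prior: alpha over the same truncated range the
    sampler's grid covers (flat reference measure, matching the grid's
    width weighting), v = lam^alpha over a wide log-spaced grid.  Empty
    clusters give 1.
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if t.size == 0:
        return 1.0
    alphas = np.linspace(alpha_lo, alpha_hi, n_alpha)
    vs = np.geomspace(1e-6, 1e6, n_v)
    log_vs = np.log(vs)
    log_t = np.log(t)
    y = delta.sum()
    log_vals = np.empty((n_alpha, n_v))
    for i, a in enumerate(alphas):
        # log f(t_i | a, lam=v^{1/a}) summed over records, per v:
        # events contribute log a - log t_i + a log t_i - log v,
        # everyone contributes -t_i^a / v
        ev = (delta * (np.log(a) - log_t + a * log_t)).sum()
        s_a = np.exp(a * log_t).sum()
        ll = ev - y * log_vs - s_a / vs
        prior_ld = ((prior.c - 1.0) * np.log(a) + a * np.log(prior.d)
                    + stats.invgamma.logpdf(vs, a=prior.a, scale=prior.b))
        log_vals[i] = ll + prior_ld
    top = log_vals.max()
    inner = np.trapezoid(np.exp(log_vals - top), vs, axis=1)
    outer = np.trapezoid(inner, alphas)
    # normalize by the truncated prior mass over the same alpha range
    prior_alpha = alphas ** (prior.c - 1.0) * prior.d ** alphas
    z_prior = np.trapezoid(prior_alpha, alphas)
    return float(outer * np.exp(top) / z_prior)


def dirichlet_multinomial_logpmf(counts, alpha_dp: float) -> float:
    """log P(c) with the weights integrated out of the truncated DP."""
    counts = np.asarray(counts, dtype=float)
    m = len(counts)
    n = counts.sum()
    a = alpha_dp / m
    return (math.lgamma(alpha_dp) - math.lgamma(alpha_dp + n)
            + sum(math.lgamma(a + c) - math.lgamma(a) for c in counts))


def enumerate_partition_posterior(x, t, delta, alpha_dp, hyper, wprior,
                                  alpha_lo, alpha_hi):
    """Exact assignment posterior over all 2^n two-component labelings.

    Returns a dict mapping label tuples to probabilities; parameters of
    both components are integrated out by quadrature (one covariate
    dimension, no regression block).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    subsets = {}
    for mask in itertools.product([0, 1], repeat=n):
        key = tuple(mask)
        idx = np.flatnonzero(mask)
        mx = normal_invchi2_marginal(x[idx], hyper.m0[0], hyper.k0,
                                     hyper.v0, hyper.s0sq[0])
        mt = weibull_cluster_marginal(t[idx], delta[idx], wprior,
                                      alpha_lo, alpha_hi)
        subsets[key] = math.log(mx) + math.log(mt)

    logpost = {}
    for labels in itertools.product([0, 1], repeat=n):
        in1 = tuple(1 if c == 1 else 0 for c in labels)
        in0 = tuple(1 - v for v in in1)
        counts = [in0.count(1), in1.count(1)]
        logpost[labels] = (dirichlet_multinomial_logpmf(counts, alpha_dp)
                           + subsets[in0] + subsets[in1])
    top = max(logpost.values())
    weights = {k: math.exp(v - top) for k, v in logpost.items()}
    z = sum(weights.values())
    return {k: w / z for k, w in weights.items()}
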