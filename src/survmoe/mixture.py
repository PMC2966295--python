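"""Truncated Dirichlet-process mixture of Weibull survival experts.

Each expert owns (i) a diagonal Normal density over the raw covariates
with a per-dimension Normal-Inv-chi^2 conjugate prior, (ii) a Weibull
survival regression with the group-lasso coefficient prior and Gaussian
random link, and (iii) its share of the mixture.  The Dirichlet process
over mixing proportions is truncated at M components (the
Dirichlet-Multinomial allocation model): weights are Dirichlet(alpha/M +
counts), and the number of occupied components is inferred rather than
fixed.  Inference is the blocked Gibbs sweep

    for each expert:  covariate params -> Weibull shape, scale
                      -> per-member eta (Laplace) -> beta, lambda_g,
                      sigma^2, rho^2
    assignments c | everything   (plug-in eta = x' beta_j per component)
    weights pi | c

A record that changes component takes the plug-in predictor of its new
expert; its latent link noise is re-drawn at the next sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .chain import PosteriorChain
from .data import SurvivalDataset
from .design import GroupedDesign
from .group_lasso import (LassoPrior, sample_beta, sample_group_scales,
                          sample_rho2, sample_sigma2)
from .weibull_posterior import (ShapeGrid, SufficientSummary, WeibullPrior,
                                sample_eta_laplace, sample_scale_given_shape,
                                sample_shape_discretized)

__all__ = [
    "CovariateHyper",
    "GibbsConfig",
    "AssignmentError",
    "sample_covariate_params",
    "sample_weights",
    "sample_assignments",
    "component_logdensity",
    "gibbs_run",
]

_EXP_MAX = 700.0
_EMPTY_SCALE_MAX = 1e4  # clamp on prior draws used to revive empty experts


class AssignmentError(RuntimeError):
    """A record has -inf log-density under every mixture component."""


@dataclass(frozen=True)
class CovariateHyper:
    """Normal-Inv-chi^2 hyperparameters of the per-dimension covariate model.

    var_d ~ Inv-chi^2(v0, s0sq_d), mu_d | var_d ~ N(m0_d, var_d / k0).
    ``from_data`` centers the prior on the empirical column means and
    variances with small k0, i.e. a weak, data-scaled prior.
    """

    m0: np.ndarray
    k0: float = 0.01
    v0: float = 1.0
    s0sq: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "m0", np.atleast_1d(np.asarray(self.m0, float)))
        s0sq = np.ones_like(self.m0) if self.s0sq is None \
            else np.atleast_1d(np.asarray(self.s0sq, float))
        object.__setattr__(self, "s0sq", s0sq)
        if self.k0 <= 0 or self.v0 <= 0 or np.any(self.s0sq <= 0):
            raise ValueError("covariate hyperparameters must be positive")

    @classmethod
    def from_data(cls, x: np.ndarray, k0: float = 0.01,
                  v0: float = 1.0) -> "CovariateHyper":
        x = np.asarray(x, dtype=float)
        var = x.var(axis=0, ddof=0)
        return cls(m0=x.mean(axis=0), k0=k0, v0=v0,
                   s0sq=np.maximum(var, 1e-6))


def sample_covariate_params(members: np.ndarray, hyper: CovariateHyper, rng):
    """Posterior (or prior, if no members) draw of per-dimension (mu, var).

    Standard Normal-Inv-chi^2 conjugate update applied independently per
    covariate dimension; an empty component draws from the prior, which is
    how empty clusters are revived.
    """
    members = np.asarray(members, dtype=float)
    d = hyper.m0.shape[0]
    k = members.shape[0] if members.ndim == 2 else 0
    if k == 0:
        var = hyper.v0 * hyper.s0sq / rng.chisquare(hyper.v0, size=d)
        mu = rng.normal(hyper.m0, np.sqrt(var / hyper.k0))
        return mu, var
    xbar = members.mean(axis=0)
    ss = ((members - xbar) ** 2).sum(axis=0)
    kn = hyper.k0 + k
    mn = (hyper.k0 * hyper.m0 + k * xbar) / kn
    vn = hyper.v0 + k
    scale = hyper.v0 * hyper.s0sq + ss + hyper.k0 * k / kn * (xbar - hyper.m0) ** 2
    var = scale / rng.chisquare(vn, size=d)
    mu = rng.normal(mn, np.sqrt(var / kn))
    return mu, var


def sample_weights(assignments, n_components: int, alpha_dp: float, rng):
    """pi ~ Dirichlet(alpha/M + n_1, ..., alpha/M + n_M)."""
    counts = np.bincount(np.asarray(assignments, dtype=int),
                         minlength=n_components)
    return rng.dirichlet(alpha_dp / n_components + counts)


def component_logdensity(x, t, delta, mus, variances, shapes, scales, etas):
    """(n, M) log joint density of each record under each expert.

    Row i, column j: log N(x_i; mu_j, var_j) + delta_i log h(t_i) - H(t_i)
    with the expert-j Weibull and linear predictor etas[i, j].
    """
    x = np.asarray(x, dtype=float)
    diff = x[:, None, :] - mus[None, :, :]
    cov = -0.5 * (np.log(2.0 * np.pi * variances)[None, :, :]
                  + diff ** 2 / variances[None, :, :]).sum(axis=2)
    logt = np.log(t)[:, None]
    z = shapes[None, :] * (logt - np.log(scales)[None, :]) + etas
    with np.errstate(over="ignore"):
        big_h = np.exp(z)  # overflow -> inf -> -inf log-density
    log_h = np.log(shapes)[None, :] - logt + z
    surv = delta[:, None] * log_h - big_h
    return cov + surv


def sample_assignments(x, t, delta, mus, variances, shapes, scales, etas,
                       pi, rng=None, u=None):
    """Draw component labels row-wise from the normalized joint densities.

    ``u`` may supply the per-row uniforms explicitly (inverse-CDF draw),
    which makes the operation exactly equivariant under row permutation.
    """
    logd = component_logdensity(x, t, delta, mus, variances, shapes, scales,
                                etas)
    with np.errstate(divide="ignore"):
        logp = logd + np.log(np.asarray(pi, dtype=float))[None, :]
    top = logp.max(axis=1)
    dead = ~np.isfinite(top)
    if np.any(dead):
        raise AssignmentError(
            f"record(s) {np.flatnonzero(dead).tolist()} have zero density "
            "under every component")
    probs = np.exp(logp - top[:, None])
    probs /= probs.sum(axis=1, keepdims=True)
    if u is None:
        if rng is None:
            raise ValueError("either rng or u must be given")
        u = rng.random(len(t))
    u = np.asarray(u, dtype=float)
    labels = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    return np.minimum(labels, probs.shape[1] - 1), logp


@dataclass
class GibbsConfig:
    """Run configuration for the blocked Gibbs sampler.

    ``n_iter`` counts total sweeps; draws after ``burn_in``, thinned by
    ``thin``, are retained.  ``link=False`` drops the regression/link
    block entirely (pure location mixture over (x, t)), which is also the
    configuration used by the small exact-enumeration cross-checks.
    """

    n_components: int = 10
    alpha_dp: float = 1.0
    n_iter: int = 2000
    burn_in: int = 200
    thin: int = 1
    seed: int = 0
    link: bool = True
    share_sigma2: bool = False
    weibull_prior: WeibullPrior = field(default_factory=WeibullPrior)
    lasso_prior: LassoPrior = field(default_factory=LassoPrior)
    shape_grid: ShapeGrid = field(default_factory=ShapeGrid)
    covariate_k0: float = 0.01
    covariate_v0: float = 1.0

    def __post_init__(self):
        if self.n_components < 1 or self.alpha_dp <= 0:
            raise ValueError("need n_components >= 1 and alpha_dp > 0")
        if not 0 <= self.burn_in <= self.n_iter:
            raise ValueError("burn_in must lie within n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _empty_regression_draw(p, group_sizes, prior: LassoPrior, rng):
    """Prior draw of the regression block for an empty expert.

    Follows the hierarchy rho^2 -> lambda_g -> sigma^2 -> beta, with the
    scale products clamped so that a heavy-tailed prior draw cannot
    produce non-finite linear predictors.
    """
    rho2 = max(rng.gamma(prior.r, 1.0 / prior.s), 1e-8)
    lam = np.minimum(rng.gamma((group_sizes + 1) / 2.0, 2.0 / rho2),
                     _EMPTY_SCALE_MAX)
    sigma2 = min(prior.nu0 * prior.s0 / rng.chisquare(prior.nu0),
                 _EMPTY_SCALE_MAX)
    beta = rng.normal(0.0, np.sqrt(np.minimum(
        sigma2 * np.repeat(lam, group_sizes), _EMPTY_SCALE_MAX)))
    return beta, lam, sigma2, rho2


def gibbs_run(dataset: SurvivalDataset, design: GroupedDesign | None,
              config: GibbsConfig) -> PosteriorChain:
    """Blocked Gibbs sampling of the truncated DP mixture of experts.

    ``design`` supplies the coded regression matrix; it must be ``None``
    exactly when ``config.link`` is False.  The chain is fully determined
    by (dataset, design, config): identical seeds give identical draws.
    With ``n_components=1`` the sweep reduces to the single-cluster
    Bayesian survival regression (assignment and weight steps are
    degenerate).
    """
    if config.link and design is None:
        raise ValueError("link model requires a design matrix")
    if not config.link and design is not None:
        raise ValueError("design given but config.link is False")

    rng = np.random.default_rng(config.seed)
    t = dataset.time
    delta = dataset.status.astype(float)
    x = dataset.covariates.to_numpy(dtype=float)
    n, n_dim = x.shape
    m = config.n_components

    if config.link:
        xd = np.ascontiguousarray(design.matrix, dtype=float)
        p = design.n_columns
        sizes = design.group_sizes
        slices = design.slices
        n_groups = design.n_groups
    else:
        xd, p, sizes, slices, n_groups = None, 0, np.empty(0, int), [], 0

    hyper = CovariateHyper.from_data(x, k0=config.covariate_k0,
                                     v0=config.covariate_v0)

    # --- state ------------------------------------------------------------
    labels = rng.integers(m, size=n)
    pi = np.full(m, 1.0 / m)
    eta = np.zeros(n)
    shapes = np.ones(m)
    scales = np.ones(m)
    mus = np.tile(hyper.m0, (m, 1))
    variances = np.tile(hyper.s0sq, (m, 1))
    betas = np.zeros((m, p))
    sigma2 = np.ones(m)
    rho2 = np.ones(m)
    lam_g = np.ones((m, n_groups))

    n_retained = max(0, (config.n_iter - config.burn_in + config.thin - 1)
                     // config.thin)
    rec = {
        "shape": np.empty((n_retained, m)), "scale": np.empty((n_retained, m)),
        "mu": np.empty((n_retained, m, n_dim)),
        "var": np.empty((n_retained, m, n_dim)),
        "pi": np.empty((n_retained, m)),
        "assignments": np.empty((n_retained, n), dtype=np.int32),
        "joint_loglik": np.empty(n_retained),
    }
    if config.link:
        rec.update({
            "beta": np.empty((n_retained, m, p)),
            "sigma2": np.empty((n_retained, m)),
            "rho2": np.empty((n_retained, m)),
            "group_scales": np.empty((n_retained, m, n_groups)),
        })

    kept = 0
    for sweep in range(config.n_iter):
        # --- per-expert parameter block (Algorithm step: Phi* | pi, c, D) --
        for j in range(m):
            idx = np.flatnonzero(labels == j)
            mus[j], variances[j] = sample_covariate_params(
                x[idx] if idx.size else np.empty((0, n_dim)), hyper, rng)
            summary = (SufficientSummary(t[idx], delta[idx], eta[idx])
                       if idx.size else SufficientSummary.empty())
            shapes[j] = sample_shape_discretized(summary, config.weibull_prior,
                                                 config.shape_grid, rng)
            scales[j] = sample_scale_given_shape(summary, shapes[j],
                                                 config.weibull_prior, rng)
            if not config.link:
                continue
            if idx.size:
                lin = xd[idx] @ betas[j]
                lam_h = np.exp(np.clip(
                    shapes[j] * (np.log(t[idx]) - np.log(scales[j])),
                    -745.0, _EXP_MAX))
                eta[idx] = sample_eta_laplace(delta[idx], lam_h, lin,
                                              sigma2[j], rng)
                betas[j] = sample_beta(xd[idx], eta[idx], lam_g[j], sizes,
                                       sigma2[j], rng)
                lam_g[j] = sample_group_scales(betas[j], sizes, slices,
                                               sigma2[j], rho2[j], rng)
                if not config.share_sigma2:
                    sigma2[j] = sample_sigma2(eta[idx], xd[idx], betas[j],
                                              lam_g[j], sizes,
                                              config.lasso_prior, rng)
                rho2[j] = sample_rho2(lam_g[j], sizes, config.lasso_prior, rng)
            else:
                betas[j], lam_g[j], s2, rho2[j] = _empty_regression_draw(
                    p, sizes, config.lasso_prior, rng)
                if not config.share_sigma2:
                    sigma2[j] = s2
        if config.link and config.share_sigma2:
            resid = eta - np.einsum("np,np->n", xd, betas[labels])
            prec = 1.0 / np.repeat(lam_g, sizes.astype(int), axis=1)
            quad = float((betas ** 2 * prec).sum())
            prior = config.lasso_prior
            df = prior.nu0 + n + m * p
            sigma2[:] = (prior.nu0 * prior.s0 + float(resid @ resid) + quad) \
                / rng.chisquare(df)

        # --- assignments (c | Phi*, pi, D) with plug-in predictors ---------
        eta_plug = xd @ betas.T if config.link else np.zeros((n, m))
        new_labels, logp = sample_assignments(
            x, t, delta, mus, variances, shapes, scales, eta_plug, pi, rng)
        moved = new_labels != labels
        eta[moved] = eta_plug[moved, new_labels[moved]]
        labels = new_labels

        # --- weights (pi | c) ---------------------------------------------
        pi = sample_weights(labels, m, config.alpha_dp, rng)

        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            rec["shape"][kept] = shapes
            rec["scale"][kept] = scales
            rec["mu"][kept] = mus
            rec["var"][kept] = variances
            rec["pi"][kept] = pi
            rec["assignments"][kept] = labels
            rec["joint_loglik"][kept] = float(logp[np.arange(n), labels].sum())
            if config.link:
                rec["beta"][kept] = betas
                rec["sigma2"][kept] = sigma2
                rec["rho2"][kept] = rho2
                rec["group_scales"][kept] = lam_g
            kept += 1
        _check_finite(sweep, shapes=shapes, scales=scales, sigma2=sigma2)

    return PosteriorChain(
        shape=rec["shape"], scale=rec["scale"], mu=rec["mu"], var=rec["var"],
        pi=rec["pi"], assignments=rec["assignments"],
        joint_loglik=rec["joint_loglik"],
        beta=rec.get("beta"), sigma2=rec.get("sigma2"),
        rho2=rec.get("rho2"), group_scales=rec.get("group_scales"),
        terms=list(design.terms) if config.link else [],
        slices=list(design.slices) if config.link else [],
        column_names=list(design.column_names) if config.link else [],
        config=config.to_dict(), seed=config.seed)


def _check_finite(sweep: int, **blocks):
    for name, arr in blocks.items():
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite draw in parameter block {name!r} at sweep {sweep}")
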