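"""Conditional-posterior samplers for the Weibull block of one expert.

The Weibull pair (shape alpha, scale lam) carries the joint conjugate
prior

    p(alpha, v) ∝ alpha^(c-1) * d^alpha * InvGamma(v; a, b),   v = lam^alpha,

whose four hyperparameters (a, b, c, d) absorb the lack of fixed-length
sufficient statistics.  Sampling alpha and lam from their mutual
conditionals mixes poorly (they are strongly correlated), so the joint
conditional is split into

* ``v | alpha``: an exact Inverse-Gamma draw (``sample_scale_given_shape``),
* ``alpha``:     its marginal with v integrated out analytically
                 (``shape_marginal_logdensity``), sampled on a discretized
                 grid (``sample_shape_discretized``).

The per-observation linear predictor ``eta_i`` has a log-concave full
conditional which is sampled by a Laplace (Gaussian) approximation at its
mode (``sample_eta_laplace``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "WeibullPrior",
    "SufficientSummary",
    "ShapeGrid",
    "DegeneratePosteriorError",
    "sample_scale_given_shape",
    "shape_marginal_logdensity",
    "sample_shape_discretized",
    "sample_eta_laplace",
]


class DegeneratePosteriorError(RuntimeError):
    """All grid log-densities are -inf: the discretized posterior is empty."""


@dataclass(frozen=True)
class WeibullPrior:
    """Hyperparameters (a, b, c, d) of the joint conjugate Weibull prior."""

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    d: float = 1.0

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) <= 0:
            raise ValueError("WeibullPrior hyperparameters must be positive")


class SufficientSummary:
    """Data summary entering the Weibull conditionals.

    Holds the member times, censoring indicators and current linear
    predictors; exposes the event count ``y``, the log product of event
    times ``log_py``, and the weighted sum S(alpha) = sum_i t_i^alpha e^{eta_i}
    (a function of alpha — the "non-fixed-length" sufficient statistic).
    """

    def __init__(self, t, delta, eta=None):
        self.t = np.asarray(t, dtype=float)
        self.delta = np.asarray(delta, dtype=float)
        if eta is None:
            eta = np.zeros_like(self.t)
        self.eta = np.asarray(eta, dtype=float)
        if not (self.t.shape == self.delta.shape == self.eta.shape):
            raise ValueError("t, delta, eta must have equal shapes")
        if np.any(self.t <= 0):
            raise ValueError("times must be strictly positive")
        self.y = float(self.delta.sum())
        self.log_py = float((self.delta * np.log(self.t)).sum())
        self._logt = np.log(self.t)

    @classmethod
    def empty(cls) -> "SufficientSummary":
        return cls(np.empty(0), np.empty(0))

    @property
    def n(self) -> int:
        return self.t.size

    def weighted_sum(self, alpha):
        """S(alpha) = sum_i t_i^alpha * exp(eta_i), vectorized over alpha."""
        alpha = np.asarray(alpha, dtype=float)
        if self.t.size == 0:
            return np.zeros(alpha.shape) if alpha.ndim else 0.0
        with np.errstate(over="ignore"):
            terms = np.exp(np.multiply.outer(alpha, self._logt) + self.eta)
        out = terms.sum(axis=-1)
        if alpha.ndim == 0:
            return float(out)
        return out


@dataclass
class ShapeGrid:
    """Log-spaced discretization of the shape axis used for sampling alpha.

    Cell weights are the geometric cell widths, so the categorical draw
    approximates the continuous marginal; refining the grid leaves the
    posterior essentially unchanged (stability is tested).  ``jitter``
    draws uniformly within the selected cell instead of returning the
    grid point, removing discretization atoms.
    """

    lo: float = 0.05
    hi: float = 30.0
    size: int = 1000
    jitter: bool = True

    def __post_init__(self):
        if not (0 < self.lo < self.hi) or self.size < 2:
            raise ValueError("invalid shape grid")

    @cached_property
    def points(self) -> np.ndarray:
        return np.geomspace(self.lo, self.hi, self.size)

    @cached_property
    def edges(self) -> np.ndarray:
        p = self.points
        inner = np.sqrt(p[:-1] * p[1:])
        return np.concatenate([[p[0]], inner, [p[-1]]])

    @cached_property
    def log_widths(self) -> np.ndarray:
        return np.log(np.diff(self.edges))


def sample_scale_given_shape(summary: SufficientSummary, alpha: float,
                             prior: WeibullPrior, rng) -> float:
    """Exact conditional draw of the scale given the shape.

    On the transformed axis v = lam^alpha the conditional is
    InvGamma(y + a, b + S(alpha)); the returned scale is v^(1/alpha).
    With no observations this reproduces the InvGamma(a, b) prior.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    shape = summary.y + prior.a
    rate = prior.b + summary.weighted_sum(alpha)
    log_v = np.log(rate) - np.log(rng.gamma(shape))
    # lam = v**(1/alpha) in log space, clamped against overflow for the
    # extreme prior draws of unoccupied components
    return float(np.exp(np.clip(log_v / alpha, -650.0, 650.0)))


def shape_marginal_logdensity(alpha, summary: SufficientSummary,
                              prior: WeibullPrior):
    """Unnormalized log marginal of the shape, scale integrated out.

    log p(alpha | ...) = (y + c - 1) log alpha + (alpha - 1) log P_y
                         + alpha log d - (y + a) log(b + S(alpha))
    where P_y is the product of event times.  Evaluated in log space;
    an overflowing S(alpha) yields -inf.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha grid must be strictly positive")
    s = summary.weighted_sum(alpha)
    with np.errstate(invalid="ignore"):
        out = ((summary.y + prior.c - 1.0) * np.log(alpha)
               + (alpha - 1.0) * summary.log_py
               + alpha * np.log(prior.d)
               - (summary.y + prior.a) * np.log(prior.b + s))
    out = np.where(np.isfinite(out), out, -np.inf)
    if alpha.ndim == 0:
        return float(out)
    return out


def sample_shape_discretized(summary: SufficientSummary, prior: WeibullPrior,
                             grid: ShapeGrid, rng) -> float:
    """Categorical draw of the shape on the discretized marginal."""
    logd = shape_marginal_logdensity(grid.points, summary, prior) + grid.log_widths
    top = logd.max()
    if not np.isfinite(top):
        raise DegeneratePosteriorError("shape marginal is -inf on the whole grid")
    probs = np.exp(logd - top)
    probs /= probs.sum()
    idx = int(np.searchsorted(np.cumsum(probs), rng.random()))
    idx = min(idx, grid.size - 1)
    if grid.jitter:
        return float(rng.uniform(grid.edges[idx], grid.edges[idx + 1]))
    return float(grid.points[idx])


def _eta_mode(delta, lam_h, mean, sigma2, max_newton=100, tol=1e-10):
    """Mode of the eta full conditional by safeguarded Newton iteration.

    Solves delta - Lam*exp(eta) - (eta - mean)/sigma2 = 0 (Lam = H(t)/e^eta
    is the hazard weight).  The objective is concave-decreasing, so from
    any start Newton lands right of the root and then converges
    monotonically; stragglers fall back to bisection, which is guaranteed
    by log-concavity.
    """
    inv_s2 = 1.0 / sigma2
    eta = np.array(mean, dtype=float, copy=True)
    upper = mean + sigma2 * delta  # root never exceeds this
    eta = np.minimum(eta, upper)
    for _ in range(max_newton):
        with np.errstate(over="ignore"):
            h = lam_h * np.exp(np.clip(eta, -745.0, 700.0))
        g = delta - h - (eta - mean) * inv_s2
        if np.all(np.abs(g) < tol):
            break
        eta = eta + g / (h + inv_s2)
    with np.errstate(over="ignore"):
        h = lam_h * np.exp(np.clip(eta, -745.0, 700.0))
    g = delta - h - (eta - mean) * inv_s2
    bad = np.abs(g) > 1e-6
    if np.any(bad):
        lo = np.where(bad, upper - 1.0, eta)
        hi = np.where(bad, upper, eta)
        for _ in range(200):
            g_lo = delta - lam_h * np.exp(np.clip(lo, -745.0, 700.0)) \
                - (lo - mean) * inv_s2
            done = g_lo > 0
            if np.all(done | ~bad):
                break
            lo = np.where(bad & ~done, lo - (hi - lo) - 1.0, lo)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            g_mid = delta - lam_h * np.exp(np.clip(mid, -745.0, 700.0)) \
                - (mid - mean) * inv_s2
            lo = np.where(g_mid > 0, mid, lo)
            hi = np.where(g_mid > 0, hi, mid)
        eta = np.where(bad, 0.5 * (lo + hi), eta)
    return eta


def sample_eta_laplace(delta, lam_h, mean, sigma2: float, rng):
    """Laplace-approximation draw from the eta full conditional.

    The target log p(eta) = delta*eta - Lam*e^eta - (eta - mean)^2/(2 sigma2)
    is strictly log-concave; the draw is Normal at the Newton mode with
    variance 1/(Lam*e^mode + 1/sigma2).  With Lam = 0 and delta = 0 this
    is an exact draw from the N(mean, sigma2) prior.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    delta, lam_h, mean = np.broadcast_arrays(
        np.asarray(delta, dtype=float), np.asarray(lam_h, dtype=float),
        np.asarray(mean, dtype=float))
    mode = _eta_mode(delta, lam_h, mean, sigma2)
    with np.errstate(over="ignore"):
        curv = lam_h * np.exp(np.clip(mode, -745.0, 700.0)) + 1.0 / sigma2
    draw = mode + rng.standard_normal(mode.shape) / np.sqrt(curv)
    if draw.ndim == 0:
        return float(draw)
    return draw
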