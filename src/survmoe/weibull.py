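"""Weibull proportional-hazards likelihood with right censoring.

The Weibull density is parametrized as

    f(t) = (alpha/lam) * (t/lam)**(alpha-1) * exp(-(t/lam)**alpha),

with shape ``alpha`` and scale ``lam``.  A linear predictor ``eta`` acts
multiplicatively on the hazard (Cox form), h(t|x) = h0(t) * exp(eta), so
the cumulative hazard is H(t|x) = (t/lam)**alpha * exp(eta).  A censored
record (delta = 0) contributes only the log-survival term -H; an event
adds log h.  All computation is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EXP_MAX = 700.0  # exp() overflow guard; larger log-hazards map to -inf loglik


@dataclass(frozen=True)
class WeibullParams:
    """Shape/scale pair of a Weibull baseline hazard; both strictly positive."""

    shape: float
    scale: float

    def __post_init__(self):
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError(f"Weibull shape must be positive, got {self.shape}")
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError(f"Weibull scale must be positive, got {self.scale}")


def _log_cum_hazard(t, params: WeibullParams, eta):
    """log H(t|x) elementwise; -inf at t = 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        return params.shape * (np.log(t) - np.log(params.scale)) + eta


def cumulative_hazard(t, params: WeibullParams, eta=0.0):
    """H(t|x) = (t/scale)**shape * exp(eta); nondecreasing in t, 0 at t = 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    z = _log_cum_hazard(t, params, eta)
    with np.errstate(over="ignore"):
        out = np.exp(np.minimum(z, _EXP_MAX))
    if np.ndim(out) == 0:
        return float(out)
    return out


def obs_loglik(t, delta, params: WeibullParams, eta=0.0):
    """Censored log-likelihood delta*log h(t|x) - H(t|x) of one or more records.

    Vectorizes over broadcastable ``t``, ``delta``, ``eta``.  Raises if the
    result is non-finite for reasons other than an overflowing hazard
    (which legitimately gives -inf).
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta)
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be strictly positive")
    z = _log_cum_hazard(t, params, eta)
    with np.errstate(over="ignore"):
        big_h = np.exp(np.minimum(z, _EXP_MAX))
    log_h = np.log(params.shape) - np.log(t) + z
    out = delta * log_h - big_h
    if np.any(np.isnan(out)):
        raise FloatingPointError("non-finite survival log-likelihood")
    if np.ndim(out) == 0:
        return float(out)
    return out


def sample_survival_time(params: WeibullParams, eta=0.0, rng=None, u=None):
    """Draw survival times by hazard inversion.

    With U ~ Uniform(0,1), t = scale * (-log U * exp(-eta))**(1/shape) has
    survival function exp(-H(t|x)).
    """
    eta = np.asarray(eta, dtype=float)
    if u is None:
        if rng is None:
            raise ValueError("either rng or u must be given")
        u = rng.random(eta.shape if eta.ndim else None)
    u = np.asarray(u, dtype=float)
    t = params.scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / params.shape)
    if np.ndim(t) == 0:
        return float(t)
    return t
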