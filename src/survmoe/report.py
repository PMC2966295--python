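"""Posterior summarization: sparsity/significance, cluster recovery,
held-out model comparison, and the Kaplan-Meier utility."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import kruskal
from sklearn.metrics import adjusted_rand_score

from .chain import PosteriorChain
from .data import SurvivalDataset
from .mixture import component_logdensity

__all__ = [
    "SignificanceSummary",
    "ComparisonResult",
    "RecoveryReport",
    "term_significance",
    "heldout_log_scores",
    "compare_models",
    "kaplan_meier",
    "cluster_recovery_report",
]


@dataclass
class SignificanceSummary:
    """Per-term posterior significance for one expert.

    ``table`` has one row per group with its sign-consistency fraction
    (max over member coefficients of max(P(beta > 0), P(beta < 0))), the
    central q-interval of the most sign-consistent member, and a
    ``significant`` flag: True when any member coefficient's central
    q-interval excludes zero.
    """

    cluster: int
    level: float
    table: pd.DataFrame

    @property
    def significant_terms(self) -> list:
        return self.table.index[self.table["significant"]].tolist()


def term_significance(chain: PosteriorChain, cluster: int,
                      q: float = 0.9) -> SignificanceSummary:
    """Empirical central-interval significance of every coefficient group."""
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    if not chain.has_regression:
        raise ValueError("chain has no regression block")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    draws = chain.beta[:, cluster, :]
    lo_q, hi_q = (1.0 - q) / 2.0, (1.0 + q) / 2.0
    rows = []
    for term, sl in zip(chain.terms, chain.slices):
        block = draws[:, sl]
        lo = np.quantile(block, lo_q, axis=0)
        hi = np.quantile(block, hi_q, axis=0)
        pos = (block > 0).mean(axis=0)
        neg = (block < 0).mean(axis=0)
        consistency = np.maximum(pos, neg)
        best = int(np.argmax(consistency))
        rows.append({
            "term": term.name,
            "order": term.order,
            "group_size": sl.stop - sl.start,
            "sign_consistency": float(consistency[best]),
            "ci_lo": float(lo[best]),
            "ci_hi": float(hi[best]),
            "significant": bool(np.any((lo > 0) | (hi < 0))),
        })
    table = pd.DataFrame(rows).set_index("term")
    return SignificanceSummary(cluster=cluster, level=q, table=table)


def heldout_log_scores(dataset: SurvivalDataset, design_matrix,
                       chain: PosteriorChain,
                       max_draws: int | None = 400) -> np.ndarray:
    """Per-record log posterior-mean predictive density.

    For each retained draw s the mixture density
    sum_j pi_j N(x; mu_j, var_j) f(t, delta | weibull_j, eta = x' beta_j)
    is evaluated; the score is the log of the across-draw average
    (Rao-Blackwellized over the retained draws, optionally thinned to
    ``max_draws`` evenly spaced ones).
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    x = dataset.covariates.to_numpy(dtype=float)
    if x.shape[1] != chain.mu.shape[2]:
        raise ValueError("covariate dimension mismatch with chain")
    t, delta = dataset.time, dataset.status.astype(float)
    if chain.has_regression:
        xd = np.asarray(design_matrix, dtype=float)
        if xd.shape[1] != chain.beta.shape[2]:
            raise ValueError("design columns mismatch with chain")
    sel = chain.draw_indices(max_draws)
    per_draw = np.empty((len(t), len(sel)))
    for k, s in enumerate(sel):
        etas = xd @ chain.beta[s].T if chain.has_regression \
            else np.zeros((len(t), chain.n_components))
        logd = component_logdensity(x, t, delta, chain.mu[s], chain.var[s],
                                    chain.shape[s], chain.scale[s], etas)
        with np.errstate(divide="ignore"):
            logd = logd + np.log(chain.pi[s])[None, :]
        per_draw[:, k] = logsumexp(logd, axis=1)
    return logsumexp(per_draw, axis=1) - np.log(len(sel))


@dataclass
class ComparisonResult:
    """Held-out comparison of the mixture model against a single-cluster fit.

    Ties in the per-point comparison count against the mixture model
    (conservative).  ``statistic``/``pvalue`` are the Kruskal-Wallis rank
    test on the two log-score samples.
    """

    scores_moe: np.ndarray
    scores_single: np.ndarray
    wins_moe: int
    wins_single: int
    statistic: float
    pvalue: float

    @property
    def n_test(self) -> int:
        return len(self.scores_moe)


def compare_models(test_set: SurvivalDataset, design_matrix,
                   chain_moe: PosteriorChain, chain_single: PosteriorChain,
                   max_draws: int | None = 400) -> ComparisonResult:
    """Score a held-out set under both chains and rank-test the scores."""
    scores_moe = heldout_log_scores(test_set, design_matrix, chain_moe,
                                    max_draws)
    scores_single = heldout_log_scores(test_set, design_matrix, chain_single,
                                       max_draws)
    wins_moe = int(np.sum(scores_moe > scores_single))
    if np.array_equal(scores_moe, scores_single):
        statistic, pvalue = 0.0, 1.0
    else:
        statistic, pvalue = kruskal(scores_moe, scores_single)
    return ComparisonResult(scores_moe=scores_moe, scores_single=scores_single,
                            wins_moe=wins_moe,
                            wins_single=len(scores_moe) - wins_moe,
                            statistic=float(statistic), pvalue=float(pvalue))


def kaplan_meier(times, deltas):
    """Product-limit survival estimate.

    Returns ``(support, survival)`` where ``support`` starts at 0 with
    survival 1 and steps at each distinct observed time; censored records
    tied with deaths leave the risk set after them.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    deltas = np.asarray(deltas, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=deltas)
    sf = fitter.survival_function_.iloc[:, 0]
    return sf.index.to_numpy(dtype=float), sf.to_numpy(dtype=float)


def km_at(support, survival, t) -> float:
    """Evaluate a step survival function at time t (right-continuous)."""
    idx = np.searchsorted(support, t, side="right") - 1
    return float(survival[max(idx, 0)])


@dataclass
class RecoveryReport:
    """Posterior-mode partition summary, optionally matched to truth.

    Occupied clusters hold more than ``threshold`` of the cohort at the
    maximum-joint-log-score retained draw.  ``matched_expert`` maps each
    generating label to the expert index with greatest member overlap
    (greedy, largest truth cluster first), and ``ari`` is the adjusted
    Rand agreement between the mode partition and the truth.
    """

    mode_iteration: int
    assignments: np.ndarray
    counts: np.ndarray
    occupied: np.ndarray
    threshold: float
    relabel: dict = field(default_factory=dict)
    matched_expert: dict | None = None
    confusion: pd.DataFrame | None = None
    ari: float | None = None

    @property
    def n_occupied(self) -> int:
        return len(self.occupied)


def cluster_recovery_report(chain: PosteriorChain, true_labels=None,
                            threshold: float = 0.05) -> RecoveryReport:
    """Summarize the posterior-mode partition of a fitted chain."""
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    mode_iter = int(np.argmax(chain.joint_loglik))
    labels = chain.assignments[mode_iter]
    n = len(labels)
    counts = np.bincount(labels, minlength=chain.n_components)
    occupied = np.flatnonzero(counts > threshold * n)
    order = occupied[np.argsort(-counts[occupied], kind="stable")]
    relabel = {int(expert): rank for rank, expert in enumerate(order)}
    report = RecoveryReport(mode_iteration=mode_iter, assignments=labels,
                            counts=counts, occupied=occupied,
                            threshold=threshold, relabel=relabel)
    if true_labels is None:
        return report

    true_labels = np.asarray(true_labels)
    truth_ids = np.unique(true_labels)
    confusion = pd.DataFrame(
        {int(j): [int(np.sum((true_labels == k) & (labels == j)))
                  for k in truth_ids]
         for j in range(chain.n_components)}, index=truth_ids)
    matched: dict = {}
    taken: set = set()
    for k in sorted(truth_ids, key=lambda k: -np.sum(true_labels == k)):
        overlaps = confusion.loc[k].drop(labels=list(taken))
        best = int(overlaps.idxmax())
        matched[int(k)] = best
        taken.add(best)
    report.matched_expert = matched
    report.confusion = confusion
    report.ari = float(adjusted_rand_score(true_labels, labels))
    return report
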