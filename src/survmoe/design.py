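"""Grouped design matrices: polynomial contrast coding and interaction expansion.

A ``K``-level ordered categorical variable is represented by ``K - 1``
orthonormal polynomial contrast columns, so an interaction of ``order + 1``
such variables uses ``(K - 1)^(order+1)`` columns instead of the
``K^(order+1)`` a dummy coding would need.  Each interaction term (a main
effect, a pair, or a triplet of variables) owns a contiguous block of
columns and forms one *group* for the group-lasso prior: selecting a
variable means selecting its whole block.

Continuous covariates contribute a single column per term (the product of
the member values), so a fully continuous expansion of ``V`` variables to
second order has ``C(V,1) + C(V,2) + C(V,3)`` single-column groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "FactorSpec",
    "InteractionTerm",
    "GroupedDesign",
    "DesignCoder",
    "polynomial_contrasts",
    "enumerate_terms",
    "build_design",
]


class DesignError(ValueError):
    """Raised for invalid factor declarations or un-declared category levels."""


@dataclass(frozen=True)
class FactorSpec:
    """Declaration of one covariate column.

    Parameters
    ----------
    name
        Column label in the input table.
    kind
        ``"continuous"`` or ``"ordered-categorical"``.
    levels
        Ordered category labels; required (>= 2, unique) for categorical
        factors and must be empty for continuous ones.
    """

    name: str
    kind: str = "continuous"
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "ordered-categorical"):
            raise DesignError(f"unknown factor kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind == "ordered-categorical":
            if len(self.levels) < 2:
                raise DesignError(
                    f"factor {self.name!r}: ordered-categorical needs >= 2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise DesignError(f"factor {self.name!r}: duplicate levels")
        elif self.levels:
            raise DesignError(f"factor {self.name!r}: continuous factor has levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class InteractionTerm:
    """A main effect or interaction: an ordered tuple of 1-3 factor names."""

    members: tuple

    def __post_init__(self):
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not 1 <= len(members) <= 3:
            raise DesignError("interaction terms have 1-3 members")
        if len(set(members)) != len(members):
            raise DesignError(f"duplicate members in term {members}")

    @property
    def order(self) -> int:
        """0 for a main effect, 1 for a pair, 2 for a triplet."""
        return len(self.members) - 1

    @property
    def name(self) -> str:
        return ":".join(self.members)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def polynomial_contrasts(n_levels: int) -> np.ndarray:
    """Orthonormal polynomial contrast matrix for equally spaced scores.

    Returns a ``(K, K-1)`` matrix whose columns are the linear, quadratic,
    ... contrasts on scores ``1..K``: every column sums to zero and the
    columns are mutually orthogonal with unit norm.  The sign convention
    makes the entry at the highest level positive (linear contrast
    increasing with level).
    """
    if n_levels < 2:
        raise DesignError(f"contrast coding needs >= 2 levels, got {n_levels}")
    scores = np.arange(1, n_levels + 1, dtype=float)
    vander = np.vander(scores, n_levels, increasing=True)
    q, _ = np.linalg.qr(vander)
    contrasts = q[:, 1:]
    sign = np.sign(contrasts[-1, :])
    sign[sign == 0] = 1.0
    return contrasts * sign


def enumerate_terms(factors, max_order: int = 2):
    """All interaction terms of the given factors up to ``max_order``.

    Order of the result is deterministic: main effects first, then pairs,
    then triplets, each block lexicographic in the declared factor order.
    """
    if max_order not in (0, 1, 2):
        raise DesignError(f"max_order must be 0, 1 or 2, got {max_order}")
    names = [f.name for f in factors]
    if not names:
        raise DesignError("at least one factor required")
    if len(set(names)) != len(names):
        raise DesignError("factor names must be unique")
    terms = []
    for size in range(1, max_order + 2):
        for combo in combinations(names, size):
            terms.append(InteractionTerm(combo))
    return terms


@dataclass
class GroupedDesign:
    """Coded design matrix plus the group structure of its columns.

    ``slices[k]`` is the contiguous column span of ``terms[k]``; the spans
    partition the columns in order.  There is no intercept column — in the
    proportional-hazards model the baseline hazard absorbs it.
    """

    matrix: np.ndarray
    terms: list = field(default_factory=list)
    slices: list = field(default_factory=list)
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        stop = 0
        for sl in self.slices:
            if sl.start != stop:
                raise DesignError("group slices must partition the columns")
            stop = sl.stop
        if stop != self.matrix.shape[1]:
            raise DesignError("group slices must cover all columns")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.terms)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([sl.stop - sl.start for sl in self.slices], dtype=int)

    @property
    def term_names(self) -> list:
        return [t.name for t in self.terms]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)


class DesignCoder:
    """Builds grouped design matrices and re-applies the same coding to new data.

    Continuous covariates are centered by default (standardization optional);
    the centering offsets are learned from the fitted table so that held-out
    data is coded in the same basis.
    """

    def __init__(self, factors, max_order: int = 2, center: bool = True,
                 standardize: bool = False):
        self.factors = list(factors)
        self.max_order = max_order
        self.center = center
        self.standardize = standardize
        self.terms = enumerate_terms(self.factors, max_order)
        self._by_name = {f.name: f for f in self.factors}
        self._offsets: dict = {}
        self._scales: dict = {}
        self._fitted = False

    def fit(self, data: pd.DataFrame) -> "DesignCoder":
        for f in self.factors:
            if f.kind == "continuous":
                col = np.asarray(data[f.name], dtype=float)
                self._offsets[f.name] = float(col.mean()) if self.center else 0.0
                if self.standardize:
                    sd = float(col.std(ddof=0))
                    if sd <= 0:
                        raise DesignError(f"factor {f.name!r}: zero variance")
                    self._scales[f.name] = sd
                else:
                    self._scales[f.name] = 1.0
        self._fitted = True
        return self

    def _base_columns(self, data: pd.DataFrame, factor: FactorSpec) -> np.ndarray:
        values = data[factor.name]
        if factor.kind == "ordered-categorical":
            index = {lvl: i for i, lvl in enumerate(factor.levels)}
            codes = np.empty(len(values), dtype=int)
            for i, v in enumerate(np.asarray(values, dtype=object)):
                if v not in index:
                    raise DesignError(
                        f"factor {factor.name!r}: level {v!r} was not declared"
                    )
                codes[i] = index[v]
            return polynomial_contrasts(factor.n_levels)[codes, :]
        col = np.asarray(values, dtype=float)
        col = (col - self._offsets[factor.name]) / self._scales[factor.name]
        return col[:, None]

    def transform(self, data: pd.DataFrame) -> GroupedDesign:
        if not self._fitted:
            raise DesignError("DesignCoder.transform called before fit")
        n = len(data)
        bases = {f.name: self._base_columns(data, f) for f in self.factors}
        blocks, slices, names = [], [], []
        start = 0
        for term in self.terms:
            cols = bases[term.members[0]]
            for m in term.members[1:]:
                b = bases[m]
                cols = (cols[:, :, None] * b[:, None, :]).reshape(n, -1)
            width = cols.shape[1]
            blocks.append(cols)
            slices.append(slice(start, start + width))
            if width == 1:
                names.append(term.name)
            else:
                names.extend(f"{term.name}[{k}]" for k in range(width))
            start += width
        matrix = np.hstack(blocks) if blocks else np.empty((n, 0))
        return GroupedDesign(matrix=matrix, terms=list(self.terms),
                             slices=slices, column_names=names)

    def fit_transform(self, data: pd.DataFrame) -> GroupedDesign:
        return self.fit(data).transform(data)


def build_design(data: pd.DataFrame, factors, max_order: int = 2,
                 center: bool = True, standardize: bool = False) -> GroupedDesign:
    """One-shot construction of a :class:`GroupedDesign` from a covariate table."""
    return DesignCoder(factors, max_order=max_order, center=center,
                       standardize=standardize).fit_transform(data)
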