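"""Retained Gibbs draws of every parameter block, with run metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class PosteriorChain:
    """Retained draws of a blocked-Gibbs run.

    Arrays are indexed ``[draw, expert, ...]``; ``beta``/``group_scales``
    are ``None`` for runs without a regression block.  ``joint_loglik`` is
    the per-draw joint log score (weights + covariate density + survival
    likelihood at the plug-in predictor) used to locate the posterior-mode
    partition.
    """

    shape: np.ndarray            # (S, M)
    scale: np.ndarray            # (S, M)
    mu: np.ndarray               # (S, M, D)
    var: np.ndarray              # (S, M, D)
    pi: np.ndarray               # (S, M)
    assignments: np.ndarray      # (S, n) int
    joint_loglik: np.ndarray     # (S,)
    beta: np.ndarray | None = None          # (S, M, p)
    sigma2: np.ndarray | None = None        # (S, M)
    rho2: np.ndarray | None = None          # (S, M)
    group_scales: np.ndarray | None = None  # (S, M, G)
    terms: list = field(default_factory=list)
    slices: list = field(default_factory=list)
    column_names: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.shape.shape[0]

    @property
    def n_components(self) -> int:
        return self.shape.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.assignments.shape[1]

    @property
    def has_regression(self) -> bool:
        return self.beta is not None

    @property
    def term_names(self) -> list:
        return [t.name for t in self.terms]

    def draw_indices(self, max_draws: int | None) -> np.ndarray:
        """Evenly spaced draw indices for posterior-mean predictive scoring."""
        s = self.n_draws
        if max_draws is None or s <= max_draws:
            return np.arange(s)
        return np.unique(np.linspace(0, s - 1, max_draws).round().astype(int))

    # --- persistence (plain CSV + JSON manifest) --------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = {
            "shape": self.shape, "scale": self.scale, "pi": self.pi,
            "joint_loglik": self.joint_loglik[:, None],
            "assignments": self.assignments,
            "mu": self.mu.reshape(self.n_draws, -1),
            "var": self.var.reshape(self.n_draws, -1),
        }
        if self.has_regression:
            flat.update({
                "beta": self.beta.reshape(self.n_draws, -1),
                "sigma2": self.sigma2, "rho2": self.rho2,
                "group_scales": self.group_scales.reshape(self.n_draws, -1),
            })
        for name, arr in flat.items():
            fmt = "%d" if arr.dtype.kind in "iu" else "%.10g"
            np.savetxt(directory / f"{name}.csv", arr, delimiter=",", fmt=fmt)
        manifest = {
            "seed": self.seed,
            "config": self.config,
            "n_draws": self.n_draws,
            "n_components": self.n_components,
            "n_subjects": self.n_subjects,
            "n_covariate_dims": self.mu.shape[2],
            "terms": [list(t.members) for t in self.terms],
            "group_slices": [[sl.start, sl.stop] for sl in self.slices],
            "column_names": list(self.column_names),
            "versions": {"numpy": np.__version__},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorChain":
        from .design import InteractionTerm

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        s, m = manifest["n_draws"], manifest["n_components"]
        d = manifest["n_covariate_dims"]

        def read(name, dtype=float):
            arr = np.loadtxt(directory / f"{name}.csv", delimiter=",",
                             dtype=dtype, ndmin=2)
            return arr

        kwargs = dict(
            shape=read("shape"), scale=read("scale"), pi=read("pi"),
            joint_loglik=read("joint_loglik")[:, 0],
            assignments=read("assignments", dtype=int),
            mu=read("mu").reshape(s, m, d), var=read("var").reshape(s, m, d),
            terms=[InteractionTerm(tuple(t)) for t in manifest["terms"]],
            slices=[slice(a, b) for a, b in manifest["group_slices"]],
            column_names=manifest["column_names"],
            config=manifest["config"], seed=manifest["seed"],
        )
        if (directory / "beta.csv").exists():
            p = len(manifest["column_names"])
            g = len(manifest["terms"])
            kwargs.update(
                beta=read("beta").reshape(s, m, p),
                sigma2=read("sigma2"), rho2=read("rho2"),
                group_scales=read("group_scales").reshape(s, m, g),
            )
        return cls(**kwargs)
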