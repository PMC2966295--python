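"""Per-subject survival records: times, censoring indicators, raw covariates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SurvivalDataset:
    """A rectangular table of right-censored survival records.

    ``status`` is 1 for an observed event and 0 for a censored record;
    times must be strictly positive (ties allowed).  ``covariates`` holds
    the raw (un-coded) covariate columns.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if self.time.shape != self.status.shape:
            raise ValueError("time and status lengths differ")
        if len(self.covariates) != len(self.time):
            raise ValueError("covariate table length differs from time")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("survival times must be strictly positive and finite")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (censored) or 1 (event)")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, time_col: str = "time",
                   status_col: str = "status", covariate_cols=None,
                   drop_missing: bool = True) -> "SurvivalDataset":
        """Build a dataset from a table; rows with missing values are rejected."""
        if covariate_cols is None:
            covariate_cols = [c for c in frame.columns
                              if c not in (time_col, status_col)]
        cols = list(covariate_cols) + [time_col, status_col]
        sub = frame[cols]
        if drop_missing:
            sub = sub.dropna()
        return cls(time=sub[time_col].to_numpy(dtype=float),
                   status=sub[status_col].to_numpy(dtype=int),
                   covariates=sub[list(covariate_cols)].copy())

    @classmethod
    def read_csv(cls, path, **kwargs) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path), **kwargs)

    def to_frame(self, extra: dict | None = None) -> pd.DataFrame:
        out = self.covariates.copy()
        out["time"] = self.time
        out["status"] = self.status
        for name, values in (extra or {}).items():
            out[name] = values
        return out

    def write_csv(self, path, extra: dict | None = None) -> None:
        self.to_frame(extra).to_csv(path, index=False)

    def subset(self, mask) -> "SurvivalDataset":
        mask = np.asarray(mask)
        return SurvivalDataset(self.time[mask], self.status[mask],
                               self.covariates.loc[mask].copy())
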