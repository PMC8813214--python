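"""Right-censored survival data container and delimited-text I/O.

One row per subject: a positive follow-up time, a 0/1 event indicator
(1 = event observed, 0 = censored), and ``p`` numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalData"]


@dataclass
class SurvivalData:
    """A right-censored survival dataset.

    Parameters
    ----------
    time
        Follow-up times, strictly positive, length ``n``.
    status
        Event indicators in {0, 1}; 1 means the event was observed.
    covariates
        ``n x p`` matrix of numeric covariates (may have ``p = 0``).
    covariate_names
        Column labels; defaults to ``x1..xp``.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = np.empty((self.time.shape[0], 0))
        n = self.time.shape[0]
        if self.status.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError(
                f"length mismatch: time {n}, status {self.status.shape[0]}, "
                f"covariates {self.covariates.shape[0]}"
            )
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all follow-up times must be finite and > 0")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must contain only 0 and 1")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariate matrix must be finite")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.covariates.shape[1])]
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length must equal number of columns")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, index: np.ndarray) -> "SurvivalData":
        """Row subset by integer index array (preserves order of ``index``)."""
        index = np.asarray(index, dtype=int)
        return SurvivalData(
            time=self.time[index],
            status=self.status[index],
            covariates=self.covariates[index],
            covariate_names=list(self.covariate_names),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.covariates, columns=self.covariate_names)
        frame.insert(0, "status", self.status)
        frame.insert(0, "time", self.time)
        return frame

    def to_csv(self, path) -> None:
        """Write ``time,status,x1..xp`` with a header row."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalData":
        """Read a dataset written by :meth:`to_csv` (or any file with
        ``time`` and ``status`` columns; remaining columns are covariates)."""
        frame = pd.read_csv(path)
        missing = {"time", "status"} - set(frame.columns)
        if missing:
            raise ValueError(f"input file lacks required column(s): {sorted(missing)}")
        names = [c for c in frame.columns if c not in ("time", "status")]
        return cls(
            time=frame["time"].to_numpy(),
            status=frame["status"].to_numpy(),
            covariates=frame[names].to_numpy() if names else np.empty((len(frame), 0)),
            covariate_names=names,
        )
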