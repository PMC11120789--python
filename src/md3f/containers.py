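"""Core data containers: feature tables, study designs, distance matrices.

A :class:`FeatureTable` holds a samples x features abundance matrix (counts or
relative abundances).  A :class:`StudyDesign` links each sample to a subject,
an observation time, and an optional group label, which is what turns a pile
of samples into longitudinal trajectories.  Distance matrices are represented
by :class:`skbio.stats.distance.DistanceMatrix`; :func:`distance_matrix`
builds one while tolerating the tiny asymmetries floating-point pipelines
produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

__all__ = ["FeatureTable", "StudyDesign", "DistanceMatrix", "distance_matrix"]

_SYM_TOL = 1e-9


@dataclass
class FeatureTable:
    """Samples x features matrix with unique string identifiers.

    Raw abundance tables must be non-negative; derived tables (e.g. CLR
    transforms, simulated displacement coordinates) may carry negative
    values and are constructed with ``allow_negative=True``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    allow_negative: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature table values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape mismatch: values are {self.values.shape} but there are "
                f"{len(self.sample_ids)} sample ids and {len(self.feature_ids)} feature ids"
            )
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {kind} id(s): {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if not self.allow_negative and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, allow_negative: bool = False) -> "FeatureTable":
        return cls(
            sample_ids=list(frame.index.astype(str)),
            feature_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            allow_negative=allow_negative,
        )

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return FeatureTable(
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            allow_negative=self.allow_negative,
        )


@dataclass
class StudyDesign:
    """Per-sample metadata: subject id, observation time, optional group.

    Stored as a data frame with columns ``sample``, ``subject``, ``time`` and
    (optionally) ``group``.  Times are non-negative reals in study units.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample", "subject", "time")

    def __post_init__(self) -> None:
        frame = pd.DataFrame(self.frame).copy()
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"design is missing required column(s): {missing}")
        frame["sample"] = frame["sample"].astype(str)
        frame["subject"] = frame["subject"].astype(str)
        frame["time"] = pd.to_numeric(frame["time"], errors="raise").astype(float)
        if "group" not in frame.columns:
            frame["group"] = None
        dupes = _duplicates(frame["sample"])
        if dupes:
            raise ValueError(f"duplicate sample id(s) in design: {sorted(dupes)}")
        if (frame["time"] < 0).any():
            bad = frame.loc[frame["time"] < 0, "sample"].iloc[0]
            raise ValueError(f"negative time for sample {bad!r}")
        if not np.all(np.isfinite(frame["time"].to_numpy())):
            raise ValueError("non-finite time in design")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample"])

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.frame["subject"]))

    def times_for(self, sample_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.frame["sample"], self.frame["time"]))
        return np.array([lookup[s] for s in sample_ids], dtype=float)

    @classmethod
    def from_records(cls, records) -> "StudyDesign":
        return cls(pd.DataFrame(records))


def distance_matrix(values: np.ndarray, ids) -> DistanceMatrix:
    """Validate and build a distance matrix.

    Requires a square matrix, symmetric within 1e-9, with a (near-)zero
    diagonal and non-negative entries.  Small floating-point asymmetries are
    averaged away; anything larger is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("distance matrix contains non-finite values")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _SYM_TOL:
        raise ValueError(f"distance matrix is asymmetric (max |D - D.T| = {asym:g})")
    sym = (values + values.T) / 2.0
    if np.abs(np.diag(sym)).max(initial=0.0) > _SYM_TOL:
        raise ValueError("distance matrix diagonal is not zero")
    np.fill_diagonal(sym, 0.0)
    if sym.min(initial=0.0) < -_SYM_TOL:
        raise ValueError("distance matrix contains negative entries")
    np.clip(sym, 0.0, None, out=sym)
    return DistanceMatrix(sym, [str(i) for i in ids])


def _duplicates(ids) -> set:
    seen: set = set()
    dup: set = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
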