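"""Delimited-text input/output and sample filtering.

Feature tables, study designs and distance matrices are plain TSV (or CSV,
by file extension) so that every artifact of an analysis is diffable and
human-inspectable.  Distance matrices use the full square layout with an id
header row and id column.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .containers import FeatureTable, StudyDesign, distance_matrix

__all__ = [
    "read_feature_table",
    "read_design",
    "read_distance_matrix",
    "write_distance_matrix",
    "filter_samples_by_sum",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(
    path,
    orientation: str = "samples_in_rows",
    allow_negative: bool = False,
) -> FeatureTable:
    """Read a delimited abundance table (one id header row, one id column).

    ``orientation`` declares which axis holds samples; the returned table is
    always samples-in-rows.  Guessing orientation from shape is deliberately
    not attempted.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orientation == "features_in_rows":
        frame = frame.T
    bad = frame.columns[~frame.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValueError(f"non-numeric values in column(s): {list(bad)}")
    return FeatureTable.from_frame(frame.astype(float), allow_negative=allow_negative)


def read_design(path) -> StudyDesign:
    """Read sample metadata with columns sample, subject, time[, group]."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    return StudyDesign(frame)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square distance matrix with id header row and id column."""
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    ids = [str(i) for i in frame.index]
    if ids != [str(c) for c in frame.columns]:
        raise ValueError("distance matrix row and column ids disagree")
    return distance_matrix(frame.to_numpy(dtype=float), ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    frame = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    frame.to_csv(path, sep=_sep_for(path), index_label="id")


def filter_samples_by_sum(table: FeatureTable, threshold: float) -> FeatureTable:
    """Drop samples whose total abundance falls below ``threshold``.

    Low-sum samples (e.g. relative-abundance rows summing well below 1)
    usually indicate failed or incompletely profiled assays; the filter is a
    plain row-sum cut on the table's own scale, with no rescaling first.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    sums = table.values.sum(axis=1)
    keep = sums >= threshold
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"sample-sum filter at {threshold} removed all {table.n_samples} samples"
        )
    logger.info(
        "sample-sum filter at %g: dropped %d of %d samples",
        threshold, n_dropped, table.n_samples,
    )
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return table.select_samples(kept_ids)


def write_table(records, path) -> None:
    """Write a result table (DataFrame or record sequence) as delimited text.

    Floats are written at full precision; rows keep their input order so the
    output is deterministic.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
    if frame.empty:
        raise ValueError("refusing to write an empty table")
    parent = os.path.dirname(str(path))
    if parent and not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    frame.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
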