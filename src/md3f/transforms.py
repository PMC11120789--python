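"""Compositional transforms, beta-diversity distances, and PCoA.

The centred log-ratio (CLR) transform maps each composition x to
log(x) - mean(log(x)), placing it in a real Euclidean space where ordinary
distances respect the relative (compositional) nature of abundance data.
The Aitchison distance is the Euclidean distance between CLR-transformed
rows.  Principal coordinate analysis (PCoA, classical MDS) embeds an
arbitrary dissimilarity matrix into Euclidean coordinates via Gower
double-centering and an eigendecomposition, which is what lets a
distance-only method operate on non-Euclidean dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .containers import FeatureTable, distance_matrix

__all__ = [
    "clr_transform",
    "compute_distances",
    "pcoa_embed",
    "PCoAEmbedding",
    "METRICS",
]

METRICS = ("euclidean", "aitchison", "bray_curtis")


def _resolve_pseudocount(values: np.ndarray, pseudocount) -> float:
    """Half the smallest positive value, if 'auto'; only applied when zeros exist."""
    if pseudocount == "auto" or pseudocount is None:
        if not np.any(values == 0):
            return 0.0
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("table is all zeros; CLR transform undefined")
        return float(positive.min() / 2.0)
    pc = float(pseudocount)
    if pc < 0:
        raise ValueError("pseudocount must be non-negative")
    return pc


def clr_transform(table: FeatureTable, pseudocount="auto") -> FeatureTable:
    """Centred log-ratio transform, row-wise.

    Each row x becomes log(x + c) - mean(log(x + c)) for pseudocount c, so
    every output row sums to zero.  ``pseudocount='auto'`` uses half the
    smallest positive value in the table, and only when zeros are present.
    """
    values = table.values
    if np.any(values < 0):
        raise ValueError("CLR transform requires non-negative abundances")
    if np.any(values.sum(axis=1) == 0):
        i = int(np.argwhere(values.sum(axis=1) == 0)[0, 0])
        raise ValueError(f"all-zero row for sample {table.sample_ids[i]!r}")
    pc = _resolve_pseudocount(values, pseudocount)
    shifted = values + pc
    if np.any(shifted == 0):
        raise ValueError("zeros present; a positive pseudocount is required")
    logs = np.log(shifted)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        values=clr,
        allow_negative=True,
    )


def compute_distances(
    table: FeatureTable, metric: str = "euclidean", pseudocount="auto"
) -> DistanceMatrix:
    """Pairwise sample dissimilarities.

    ``aitchison`` is the Euclidean distance computed after a CLR transform;
    ``bray_curtis`` requires rows with positive sums.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to compute distances")
    if metric == "euclidean":
        condensed = pdist(table.values, metric="euclidean")
    elif metric == "aitchison":
        condensed = pdist(clr_transform(table, pseudocount).values, metric="euclidean")
    else:
        if np.any(table.values.sum(axis=1) == 0):
            raise ValueError("Bray-Curtis is undefined for rows summing to zero")
        condensed = pdist(table.values, metric="braycurtis")
    return distance_matrix(squareform(condensed), table.sample_ids)


@dataclass
class PCoAEmbedding:
    """Euclidean coordinates recovered from a dissimilarity matrix.

    ``coordinates`` has one column per retained (positive-eigenvalue) axis,
    scaled so that pairwise Euclidean distances among rows reproduce the
    input distances whenever those were Euclidean to begin with.
    """

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    n_dropped_negative: int

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa_embed(dist, max_axes: int | None = None) -> PCoAEmbedding:
    """Classical multidimensional scaling of a distance matrix.

    Double-centres -D^2/2 (Gower), eigendecomposes, and keeps axes with
    eigenvalue above max(n,1)*eps*lambda_max.  Negative-eigenvalue axes
    (non-Euclidean dissimilarities) are dropped and counted, without
    Cailliez/Lingoes correction.  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    if isinstance(dist, DistanceMatrix):
        D = dist.data
        ids = list(dist.ids)
    else:
        D = np.asarray(dist, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance input must be square")
        if np.abs(D - D.T).max(initial=0.0) > 1e-9:
            raise ValueError("distance input is asymmetric")
        ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for PCoA")

    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(n, 1) * np.finfo(float).eps * max(eigvals.max(initial=0.0), 0.0)
    n_dropped_negative = int((eigvals < -tol).sum())
    if n_dropped_negative:
        warnings.warn(
            f"PCoA dropped {n_dropped_negative} negative-eigenvalue axis/axes "
            "(non-Euclidean dissimilarity)",
            stacklevel=2,
        )
    keep = eigvals > tol
    vals = eigvals[keep]
    vecs = eigvecs[:, keep]
    coords = vecs * np.sqrt(vals)
    # reproducible sign: largest-magnitude loading positive on each axis
    for j in range(coords.shape[1]):
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    if max_axes is not None and coords.shape[1] > max_axes:
        coords = coords[:, :max_axes]
        vals = vals[:max_axes]
    return PCoAEmbedding(
        ids=ids,
        coordinates=coords,
        eigenvalues=vals,
        n_dropped_negative=n_dropped_negative,
    )
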