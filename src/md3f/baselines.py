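"""Univariate and ordination-based comparison methods.

These are the bottom-up alternatives a practitioner might reach for when
asking "does this multivariate profile depend on time?": regress each
feature (or each principal coordinate) on time and take the smallest
p-value, with or without a multiplicity adjustment.  They are included as
comparators, faithfully reproducing their usual form — in particular the
PCo2/PCoA variants take the raw minimum over per-axis p-values without any
correction, which is part of why they are anticonservative and must not be
"fixed" here.

Methods
-------
PCo1 / PCo2 / PCoA : regress the first 1 / first 2 / all retained principal
    coordinates on time; overall p is the minimum per-axis p-value.
uFDR / uHolm : regress every feature on time; overall p is the minimum
    Benjamini-Hochberg (resp. Holm) adjusted p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable
from .transforms import PCoAEmbedding, pcoa_embed

__all__ = [
    "BaselineResult",
    "pco_regression_test",
    "univariate_screen_test",
    "slope_pvalues",
    "evaluate_prepost_baselines",
    "BASELINE_METHODS",
]

BASELINE_METHODS = ("PCo1", "PCo2", "PCoA", "uFDR", "uHolm")


@dataclass
class BaselineResult:
    method: str
    per_test_p: np.ndarray
    overall_p: float
    n_tests: int


def slope_pvalues(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided coefficient t-test p-values of OLS slope, per column of Y.

    Closed-form simple regression of every column of Y on the shared
    regressor x.  Columns with (numerically) zero residual and zero slope
    variance — constant features — get p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations for a slope test")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("time values are all equal; slope undefined")
    Yc = Y - Y.mean(axis=0)
    sxy = xc @ Yc
    syy = np.einsum("ij,ij->j", Yc, Yc)
    slope = sxy / sxx
    rss = np.maximum(syy - slope * sxy, 0.0)
    se2 = rss / ((n - 2) * sxx)
    pvals = np.empty(Y.shape[1])
    zero_se = se2 <= 0
    constant = zero_se & (np.abs(slope) < 1e-300)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); p-value set to 1",
            stacklevel=2,
        )
    pvals[constant] = 1.0
    exact = zero_se & ~constant  # perfect non-flat linear fit
    pvals[exact] = 0.0
    ok = ~zero_se
    tstat = slope[ok] / np.sqrt(se2[ok])
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return pvals


def pco_regression_test(
    embedding: PCoAEmbedding, times: np.ndarray, k="all"
) -> BaselineResult:
    """Regress the first k retained principal coordinates on time.

    Overall p is the raw minimum over the per-axis coefficient-test
    p-values (no multiplicity adjustment, by construction of the method).
    """
    times = np.asarray(times, dtype=float)
    if len(times) != embedding.coordinates.shape[0]:
        raise ValueError("times and embedding are not aligned")
    n_axes = embedding.n_axes
    if n_axes == 0:
        warnings.warn("embedding has no retained axes; p set to 1", stacklevel=2)
        return BaselineResult("PCoA", np.array([]), 1.0, 0)
    if k == "all":
        use = n_axes
    else:
        use = int(k)
        if use < 1:
            raise ValueError("k must be >= 1 or 'all'")
        if use > n_axes:
            warnings.warn(
                f"requested {use} axes but only {n_axes} retained; using all",
                stacklevel=2,
            )
            use = n_axes
    pvals = slope_pvalues(times, embedding.coordinates[:, :use])
    method = {1: "PCo1", 2: "PCo2"}.get(use if k != "all" else -1, "PCoA")
    return BaselineResult(method, pvals, float(pvals.min()), use)


def univariate_screen_test(
    table, times: np.ndarray, adjust: str = "fdr"
) -> BaselineResult:
    """Per-feature regression on time with FDR (BH) or Holm adjustment.

    Overall p is the minimum adjusted p-value, the usual "any feature moves
    with time" screen.
    """
    if adjust not in ("fdr", "holm"):
        raise ValueError("adjust must be 'fdr' or 'holm'")
    values = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    times = np.asarray(times, dtype=float)
    if len(times) != values.shape[0]:
        raise ValueError("times and table are not aligned")
    raw = slope_pvalues(times, values)
    method = "fdr_bh" if adjust == "fdr" else "holm"
    adjusted = multipletests(raw, method=method)[1]
    name = "uFDR" if adjust == "fdr" else "uHolm"
    return BaselineResult(name, adjusted, float(adjusted.min()), len(adjusted))


def evaluate_prepost_baselines(
    displacements: np.ndarray,
    times: np.ndarray,
    methods=BASELINE_METHODS,
    include_origin: bool = False,
) -> dict[str, float]:
    """Overall p-value of each baseline on one pre/post dataset.

    By default only the follow-up displacement vectors enter (the baseline
    rows sit at the origin at time 0 and would be constant); pass
    ``include_origin=True`` to add them.  Shared work (per-feature p-values,
    the PCoA embedding) is computed once across the requested methods.
    """
    X = np.asarray(displacements, dtype=float)
    t = np.asarray(times, dtype=float)
    if include_origin:
        X = np.vstack([np.zeros_like(X), X])
        t = np.concatenate([np.zeros_like(t), t])
    out: dict[str, float] = {}
    unknown = [m for m in methods if m not in BASELINE_METHODS]
    if unknown:
        raise ValueError(f"unknown baseline method(s): {unknown}")
    if "uFDR" in methods or "uHolm" in methods:
        raw = slope_pvalues(t, X)
        if "uFDR" in methods:
            out["uFDR"] = float(multipletests(raw, method="fdr_bh")[1].min())
        if "uHolm" in methods:
            out["uHolm"] = float(multipletests(raw, method="holm")[1].min())
    pco_methods = [m for m in methods if m.startswith("PCo")]
    if pco_methods:
        D = _euclidean_square(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = pcoa_embed(D)
            for m in pco_methods:
                k = {"PCo1": 1, "PCo2": 2, "PCoA": "all"}[m]
                out[m] = pco_regression_test(emb, t, k=k).overall_p
    return {m: out[m] for m in methods}


def _euclidean_square(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X, metric="euclidean"))
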