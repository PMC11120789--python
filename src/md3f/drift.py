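"""Drift-magnitude estimation from interpoint distances (the MD3F core).

A multivariate trajectory following a drift-diffusion process with drift
magnitude alpha satisfies

    E[ dist(M_s, M_{s+t})^2 ] = alpha^2 t^2 + (diffusion term linear in t),

so the squared interpoint distance, once scaled by the time interval,
depends linearly on the interval with slope alpha^2.  MD3F therefore needs
nothing but (time interval, distance) pairs: an ordinary least-squares fit
of the time-scaled squared distance on the interval estimates beta = alpha^2
(``linear2`` model), and the coefficient t-test on the slope tests for the
presence of drift.  A simpler unsquared variant (``linear``: distance on
time) is provided for comparison; it is biased upward in high dimensions
because E[d] grows with sqrt(d t) even without drift.

Two response scalings are available for each model.  ``time_scaled`` (the
default) regresses d^2/t on t (or d/sqrt(t) on sqrt(t)), which makes the
diffusion contribution an intercept and leaves the null slope at zero.
``literal`` regresses d^2 on t^2 (or d on t); under diffusion the d*t term
then loads on the slope, so the literal forms are mis-specified under the
null and are kept only for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .containers import StudyDesign

__all__ = [
    "PairSet",
    "MD3FFit",
    "GroupComparison",
    "PerSubjectFits",
    "build_pairs",
    "fit_md3f",
    "fit_pairs_arrays",
    "fit_per_subject",
    "compare_group_drifts",
    "PAIR_MODES",
    "MODELS",
    "SCALINGS",
]

PAIR_MODES = ("baseline", "consecutive", "all_pairs")
MODELS = ("linear2", "linear")
SCALINGS = ("time_scaled", "literal")


@dataclass
class PairSet:
    """(time interval, interpoint distance) observations pooled over subjects."""

    delta_t: np.ndarray
    distance: np.ndarray
    subject: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        self.subject = np.asarray(self.subject, dtype=object)
        if not (len(self.delta_t) == len(self.distance) == len(self.subject)):
            raise ValueError("pair arrays must have equal length")
        if len(self.delta_t) < 1:
            raise ValueError("a pair set needs at least one pair")
        if np.any(self.delta_t <= 0):
            raise ValueError("all time intervals must be positive")
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")
        if self.mode not in PAIR_MODES:
            raise ValueError(f"unknown pair mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.delta_t)


@dataclass
class MD3FFit:
    """OLS fit of the drift model on a pair set.

    ``slope`` estimates beta = alpha^2 for the linear2 model (alpha for
    linear); ``intercept`` absorbs the time-free diffusion contribution;
    ``alpha_hat`` is the drift-magnitude estimate, clipped at zero since a
    magnitude cannot be negative (the raw slope is still reported).
    """

    model: str
    scaling: str
    slope: float
    intercept: float
    residual_variance: float
    slope_se: float
    slope_p: float
    alpha_hat: float
    n_pairs: int


@dataclass
class GroupComparison:
    """Two-sample Student t-test on per-subject drift estimates."""

    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    t_statistic: float
    p_value: float
    n_per_group: tuple[int, int]


@dataclass
class PerSubjectFits:
    """Per-subject fits plus subjects skipped for having too few pairs."""

    fits: dict[str, MD3FFit]
    skipped: dict[str, str]

    def to_records(self) -> list[dict]:
        rows = []
        for subject, fit in self.fits.items():
            rows.append(
                {
                    "subject": subject,
                    "model": fit.model,
                    "scaling": fit.scaling,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "alpha_hat": fit.alpha_hat,
                    "residual_variance": fit.residual_variance,
                    "slope_se": fit.slope_se,
                    "slope_p": fit.slope_p,
                    "n_pairs": fit.n_pairs,
                }
            )
        return rows


def build_pairs(
    dist: DistanceMatrix,
    design: StudyDesign,
    mode: str = "baseline",
    dedupe: str = "error",
) -> PairSet:
    """Extract (time interval, distance) pairs from per-subject trajectories.

    Per subject, with samples sorted by time: ``baseline`` pairs every later
    sample with the first one (intervals measured from the start of the
    walk); ``consecutive`` pairs neighbouring samples; ``all_pairs`` takes
    every ordered pair.  Subjects with fewer than two timepoints are skipped
    with a warning.  Duplicate (subject, time) records are an error unless
    ``dedupe='first'`` keeps the first occurrence.
    """
    if mode not in PAIR_MODES:
        raise ValueError(f"unknown pair mode {mode!r}; choose from {PAIR_MODES}")
    if dedupe not in ("error", "first"):
        raise ValueError("dedupe must be 'error' or 'first'")
    id_pos = {s: i for i, s in enumerate(dist.ids)}
    missing = [s for s in design.sample_ids if s not in id_pos]
    if missing:
        raise ValueError(f"design sample(s) absent from distance matrix: {missing[:5]}")

    D = dist.data
    dts: list[float] = []
    ds: list[float] = []
    subj: list[str] = []
    for subject, sub in design.frame.groupby("subject", sort=True):
        sub = sub.sort_values("time", kind="stable")
        times = sub["time"].to_numpy()
        samples = list(sub["sample"])
        if len(np.unique(times)) != len(times):
            if dedupe == "error":
                raise ValueError(
                    f"subject {subject!r} has duplicate observation times; "
                    "pass dedupe='first' to keep the first sample at each time"
                )
            _, first_idx = np.unique(times, return_index=True)
            first_idx = np.sort(first_idx)
            times = times[first_idx]
            samples = [samples[i] for i in first_idx]
        if len(times) < 2:
            warnings.warn(
                f"subject {subject!r} has fewer than 2 timepoints; skipped",
                stacklevel=2,
            )
            continue
        idx = [id_pos[s] for s in samples]
        if mode == "baseline":
            pairs = [(0, k) for k in range(1, len(times))]
        elif mode == "consecutive":
            pairs = [(k - 1, k) for k in range(1, len(times))]
        else:
            pairs = [(i, k) for i in range(len(times)) for k in range(i + 1, len(times))]
        for i, k in pairs:
            dts.append(times[k] - times[i])
            ds.append(D[idx[i], idx[k]])
            subj.append(str(subject))
    if not dts:
        raise ValueError("no usable pairs: every subject has fewer than 2 timepoints")
    return PairSet(np.array(dts), np.array(ds), np.array(subj, dtype=object), mode)


def fit_pairs_arrays(
    delta_t: np.ndarray,
    distance: np.ndarray,
    model: str = "linear2",
    scaling: str = "time_scaled",
) -> MD3FFit:
    """Fit the drift regression directly on raw pair arrays (fast path)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if scaling not in SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")
    t = np.asarray(delta_t, dtype=float)
    d = np.asarray(distance, dtype=float)
    n = len(t)
    if n < 3:
        raise ValueError(f"need at least 3 pairs to fit (slope, intercept, residual); got {n}")
    if np.any(t <= 0):
        raise ValueError("all time intervals must be positive")

    if model == "linear2":
        x, y = (t, d**2 / t) if scaling == "time_scaled" else (t**2, d**2)
    else:
        rt = np.sqrt(t)
        x, y = (rt, d / rt) if scaling == "time_scaled" else (t, d)

    if np.ptp(x) == 0:
        raise ValueError("regressor has zero variance (all time intervals equal)")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    residual_variance = float(resid @ resid / (n - 2))
    slope = float(res.slope)
    alpha_hat = float(np.sqrt(max(slope, 0.0)) if model == "linear2" else max(slope, 0.0))
    return MD3FFit(
        model=model,
        scaling=scaling,
        slope=slope,
        intercept=float(res.intercept),
        residual_variance=residual_variance,
        slope_se=float(res.stderr),
        slope_p=float(res.pvalue),
        alpha_hat=alpha_hat,
        n_pairs=n,
    )


def fit_md3f(
    pairs: PairSet, model: str = "linear2", scaling: str = "time_scaled"
) -> MD3FFit:
    """Fit the drift-magnitude regression on a pair set.

    Within-subject dependence between pairs is deliberately ignored: the
    estimator treats pooled pairs as exchangeable regression observations.
    """
    return fit_pairs_arrays(pairs.delta_t, pairs.distance, model=model, scaling=scaling)


def fit_per_subject(
    dist: DistanceMatrix,
    design: StudyDesign,
    mode: str = "baseline",
    model: str = "linear2",
    scaling: str = "time_scaled",
    dedupe: str = "error",
) -> PerSubjectFits:
    """One drift fit per subject; subjects with < 3 usable pairs are skipped."""
    fits: dict[str, MD3FFit] = {}
    skipped: dict[str, str] = {}
    for subject in design.subjects:
        sub_design = StudyDesign(design.frame[design.frame["subject"] == subject])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pairs = build_pairs(dist, sub_design, mode=mode, dedupe=dedupe)
        except ValueError:
            skipped[subject] = "insufficient pairs"
            continue
        if len(pairs) < 3:
            skipped[subject] = "insufficient pairs"
            continue
        fits[subject] = fit_md3f(pairs, model=model, scaling=scaling)
    if not fits:
        raise ValueError("no subject has enough pairs to fit the drift model")
    return PerSubjectFits(fits=fits, skipped=skipped)


def compare_group_drifts(fits: PerSubjectFits, design: StudyDesign) -> GroupComparison:
    """Student (pooled-variance) t-test of per-subject drift estimates between groups."""
    group_of = (
        design.frame.drop_duplicates("subject").set_index("subject")["group"].to_dict()
    )
    by_group: dict[str, list[float]] = {}
    for subject, fit in fits.fits.items():
        g = group_of.get(subject)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            raise ValueError(f"subject {subject!r} has no group label")
        by_group.setdefault(str(g), []).append(fit.alpha_hat)
    if len(by_group) != 2:
        raise ValueError(
            f"group comparison needs exactly 2 groups, found {sorted(by_group)}"
        )
    (g1, v1), (g2, v2) = sorted(by_group.items())
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs at least 2 fitted subjects")
    a1, a2 = np.array(v1), np.array(v2)
    if np.var(a1, ddof=1) == 0 and np.var(a2, ddof=1) == 0:
        # degenerate: no within-group variance; equal means -> no evidence
        equal = np.isclose(a1.mean(), a2.mean())
        t_stat, p = (0.0, 1.0) if equal else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(a1, a2, equal_var=True)
    return GroupComparison(
        group_labels=(g1, g2),
        group_means=(float(a1.mean()), float(a2.mean())),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_per_group=(len(v1), len(v2)),
    )
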