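"""Drift-diffusion simulators for validating distance-based inference.

Two generators are provided.  ``simulate_prepost`` emulates the common
two-timepoint longitudinal design: each subject has a baseline observation
at the multivariate origin at time 0 and a follow-up at a subject-specific
time s drawn from an exponential distribution, with displacement

    X | s  ~  Normal( alpha * s * direction,  s * I ),

so that the squared mean displacement norm is (alpha*s)^2 and the diffusion
contributes variance s per coordinate.  The default direction 1_d/sqrt(d)
spreads the drift equally over all dimensions; since only distances enter
the downstream analysis, any other unit direction gives the same answers.

``simulate_trajectory`` produces a full multi-step random walk with
Gaussian increments of mean alpha*dt*direction and covariance dt*I per
step, for studying designs with many timepoints per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, StudyDesign

__all__ = [
    "SimulationScenario",
    "PrePostSample",
    "TrajectoryRealization",
    "simulate_prepost",
    "simulate_trajectory",
    "replicate_rng",
]


def replicate_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: replicate (and grid-cell) indices form the spawn key.

    Streams depend only on (seed, key), never on evaluation order, so grids
    are reproducible cell-by-cell and safely parallelizable.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class SimulationScenario:
    """Parameters of one simulated condition.

    n: subjects; d: dimensions; alpha: drift magnitude (0 = pure diffusion);
    time_rate: rate of the exponential distribution of follow-up times
    (mean interval 1/time_rate); direction: unit drift direction, default
    1_d/sqrt(d).
    """

    n: int
    d: int
    alpha: float
    time_rate: float = 1.0
    seed: int | None = None
    direction: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 subjects")
        if self.d < 1:
            raise ValueError("need at least 1 dimension")
        if self.alpha < 0:
            raise ValueError("drift magnitude must be non-negative")
        if self.time_rate <= 0:
            raise ValueError("exponential time rate must be positive")
        if self.direction is None:
            self.direction = np.full(self.d, 1.0 / np.sqrt(self.d))
        else:
            v = np.asarray(self.direction, dtype=float)
            if v.shape != (self.d,):
                raise ValueError(f"direction must have length d={self.d}")
            norm = float(np.linalg.norm(v))
            if norm == 0:
                raise ValueError("direction must be a non-zero vector")
            if abs(norm - 1.0) > 1e-9:
                warnings.warn("direction is not unit length; normalizing", stacklevel=2)
                v = v / norm
            self.direction = v

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PrePostSample:
    """One realization of the pre/post design.

    ``times`` are the per-subject follow-up intervals s; ``displacements``
    are the post positions (pre is at the origin).
    """

    times: np.ndarray
    displacements: np.ndarray
    scenario: SimulationScenario

    def distances(self) -> np.ndarray:
        """Euclidean interpoint distance per subject (post vs. origin)."""
        return np.linalg.norm(self.displacements, axis=1)

    def subject_ids(self) -> list[str]:
        width = len(str(self.scenario.n))
        return [f"subj{i + 1:0{width}d}" for i in range(self.scenario.n)]

    def to_feature_table(self) -> FeatureTable:
        """Samples x dimensions view: pre rows at the origin, post rows at X."""
        subjects = self.subject_ids()
        ids = [f"{s}.pre" for s in subjects] + [f"{s}.post" for s in subjects]
        values = np.vstack(
            [np.zeros_like(self.displacements), self.displacements]
        )
        features = [f"dim{j + 1}" for j in range(self.scenario.d)]
        return FeatureTable(ids, features, values, allow_negative=True)

    def to_design(self) -> StudyDesign:
        subjects = self.subject_ids()
        frame = pd.DataFrame(
            {
                "sample": [f"{s}.pre" for s in subjects] + [f"{s}.post" for s in subjects],
                "subject": subjects + subjects,
                "time": np.concatenate([np.zeros(self.scenario.n), self.times]),
            }
        )
        return StudyDesign(frame)


@dataclass
class TrajectoryRealization:
    """A multi-step random-walk path: times (0, dt, ..., n*dt) and positions."""

    times: np.ndarray
    positions: np.ndarray
    scenario: SimulationScenario

    def baseline_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(interval from start, Euclidean distance from start) for each later timepoint."""
        d = np.linalg.norm(self.positions[1:] - self.positions[0], axis=1)
        return self.times[1:] - self.times[0], d


def simulate_prepost(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> PrePostSample:
    """Draw one pre/post dataset: s ~ Exp(rate), X | s ~ N(alpha*s*dir, s*I)."""
    if rng is None:
        rng = scenario.rng()
    s = rng.exponential(scale=1.0 / scenario.time_rate, size=scenario.n)
    mean = scenario.alpha * s[:, None] * scenario.direction[None, :]
    noise = rng.standard_normal((scenario.n, scenario.d))
    displacements = mean + np.sqrt(s)[:, None] * noise
    return PrePostSample(times=s, displacements=displacements, scenario=scenario)


def simulate_trajectory(
    scenario: SimulationScenario,
    n_steps: int,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> TrajectoryRealization:
    """Draw one random-walk path of ``n_steps`` Gaussian increments from the origin."""
    if n_steps < 1:
        raise ValueError("need at least 1 step")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = scenario.rng()
    increments = (
        scenario.alpha * dt * scenario.direction[None, :]
        + np.sqrt(dt) * rng.standard_normal((n_steps, scenario.d))
    )
    positions = np.vstack([np.zeros(scenario.d), np.cumsum(increments, axis=0)])
    times = np.arange(n_steps + 1, dtype=float) * dt
    return TrajectoryRealization(times=times, positions=positions, scenario=scenario)
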