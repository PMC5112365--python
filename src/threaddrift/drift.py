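"""Similarity trajectories, positional baselines and drift classification.

The drift detector is deliberately simple: every post at position p >= 2
gets its cosine similarity to the thread's original post; the corpus-wide
mean of those scores at each position (restricted to positions with
enough support) is the baseline; a post whose score falls strictly below
the baseline at its own position (minus an optional margin) is classified
as topic drift.  A logarithmic trend fitted to the baseline summarizes
the gradual-drift pattern of a corpus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .corpus import Thread
from .textvec import CommunityTfidf, cosine

__all__ = [
    "TrajectoryPoint",
    "SimilarityTrajectory",
    "PositionBaseline",
    "DriftLabel",
    "TrendFit",
    "BaselineUndefinedError",
    "trajectory",
    "position_baseline",
    "classify_drift",
    "fit_log_trend",
    "PositionBaselineDriftClassifier",
    "labels_to_frame",
]

DEFAULT_MIN_SUPPORT = 50  # figure-construction rule: positions with >= 50 posts


class BaselineUndefinedError(KeyError):
    """Raised when classifying at a position the baseline does not cover."""


@dataclass(frozen=True)
class TrajectoryPoint:
    position: int
    sim_to_first: float
    sim_to_prev: float


@dataclass(frozen=True)
class SimilarityTrajectory:
    """Cosine similarities of a thread's replies, positions 2..L."""

    thread_id: str
    points: tuple[TrajectoryPoint, ...]

    def sim_to_first(self) -> dict[int, float]:
        return {pt.position: pt.sim_to_first for pt in self.points}


@dataclass(frozen=True)
class PositionBaseline:
    """Mean similarity-to-first per position, with contributor counts."""

    means: Mapping[int, float]
    counts: Mapping[int, int]
    min_support: int

    def __contains__(self, position: int) -> bool:
        return position in self.means

    def positions(self) -> list[int]:
        return sorted(self.means)

    def mean(self, position: int) -> float:
        try:
            return self.means[position]
        except KeyError:
            raise BaselineUndefinedError(
                f"no baseline at position {position}: fewer than "
                f"{self.min_support} contributing posts; lower min_support "
                "or supply a fallback"
            )


@dataclass(frozen=True)
class DriftLabel:
    thread_id: str
    position: int
    score: float
    baseline: float
    is_drift: bool


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of baseline means on ln(position): y = slope*ln(x) + intercept."""

    slope: float
    intercept: float
    r_squared: float


def trajectory(thread: Thread, model: CommunityTfidf) -> SimilarityTrajectory:
    """Similarity trajectory of one thread under a fitted tf-idf model."""
    if len(thread) < 2:
        raise ValueError(f"thread {thread.thread_id}: need >= 2 posts for a trajectory")
    vectors = [model.transform_one(p) for p in thread.posts]
    points = tuple(
        TrajectoryPoint(
            position=i + 1,
            sim_to_first=cosine(vectors[i], vectors[0]),
            sim_to_prev=cosine(vectors[i], vectors[i - 1]),
        )
        for i in range(1, len(vectors))
    )
    return SimilarityTrajectory(thread_id=thread.thread_id, points=points)


def position_baseline(
    trajectories: Iterable[SimilarityTrajectory],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> PositionBaseline:
    """Arithmetic mean of sim_to_first per position, keeping positions with
    at least ``min_support`` contributing posts."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for traj in trajectories:
        for pt in traj.points:
            sums[pt.position] = sums.get(pt.position, 0.0) + pt.sim_to_first
            counts[pt.position] = counts.get(pt.position, 0) + 1
    means = {
        pos: sums[pos] / counts[pos]
        for pos in sums
        if counts[pos] >= min_support
    }
    if not means:
        warnings.warn(
            f"no position reaches min_support={min_support}; baseline is empty",
            stacklevel=2,
        )
    kept_counts = {pos: counts[pos] for pos in means}
    return PositionBaseline(means=means, counts=kept_counts, min_support=min_support)


def classify_drift(
    point: TrajectoryPoint,
    baseline: PositionBaseline,
    margin: float = 0.0,
    thread_id: str = "",
) -> DriftLabel:
    """Label a trajectory point as drift iff score < baseline mean - margin.

    Ties are not drift (strict inequality).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    mean = baseline.mean(point.position)
    return DriftLabel(
        thread_id=thread_id,
        position=point.position,
        score=point.sim_to_first,
        baseline=mean,
        is_drift=point.sim_to_first < mean - margin,
    )


def fit_log_trend(baseline: PositionBaseline) -> TrendFit:
    """Least-squares fit of baseline means against ln(position)."""
    positions = baseline.positions()
    if len(positions) < 3:
        raise ValueError(
            f"need >= 3 baseline positions for a trend fit, got {len(positions)}"
        )
    x = np.log(np.asarray(positions, dtype=float))
    y = np.asarray([baseline.means[p] for p in positions], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # constant y: OLS reproduces it exactly (up to rounding), define R^2 = 1
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return TrendFit(slope=float(slope), intercept=float(intercept), r_squared=r_squared)


class PositionBaselineDriftClassifier(BaseEstimator, ClassifierMixin):
    """Drift classifier with the positional mean as decision threshold.

    ``fit`` consumes similarity trajectories and stores the positional
    baseline; ``predict`` labels (position, sim_to_first) pairs or whole
    trajectories.  Positions the baseline does not cover raise
    :class:`BaselineUndefinedError` unless ``on_missing='skip'``.
    """

    def __init__(self, min_support: int = DEFAULT_MIN_SUPPORT, margin: float = 0.0):
        self.min_support = min_support
        self.margin = margin

    def fit(self, X: Iterable[SimilarityTrajectory], y=None):
        self.baseline_ = position_baseline(X, min_support=self.min_support)
        self.trend_ = None
        return self

    def _check_fitted(self):
        if not hasattr(self, "baseline_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    def predict(self, X: Sequence[tuple[int, float]]) -> np.ndarray:
        """Boolean drift predictions for (position, sim_to_first) pairs."""
        self._check_fitted()
        out = []
        for position, score in X:
            mean = self.baseline_.mean(int(position))
            out.append(score < mean - self.margin)
        return np.asarray(out, dtype=bool)

    def label_trajectories(
        self,
        trajectories: Iterable[SimilarityTrajectory],
        on_missing: str = "error",
    ) -> list[DriftLabel]:
        """DriftLabels for every covered point of the given trajectories."""
        self._check_fitted()
        if on_missing not in {"error", "skip"}:
            raise ValueError("on_missing must be 'error' or 'skip'")
        labels = []
        for traj in trajectories:
            for pt in traj.points:
                if pt.position not in self.baseline_:
                    if on_missing == "skip":
                        continue
                    self.baseline_.mean(pt.position)  # raises
                labels.append(
                    classify_drift(
                        pt, self.baseline_, margin=self.margin, thread_id=traj.thread_id
                    )
                )
        return labels

    def log_trend(self) -> TrendFit:
        self._check_fitted()
        if self.trend_ is None:
            self.trend_ = fit_log_trend(self.baseline_)
        return self.trend_


def labels_to_frame(
    labels: Iterable[DriftLabel],
    trajectories: Iterable[SimilarityTrajectory] | None = None,
) -> pd.DataFrame:
    """Tabular export: thread_id, position, sim_to_first, sim_to_prev,
    baseline, is_drift (sim_to_prev filled when trajectories are given)."""
    prev: dict[tuple[str, int], float] = {}
    if trajectories is not None:
        for traj in trajectories:
            for pt in traj.points:
                prev[(traj.thread_id, pt.position)] = pt.sim_to_prev
    rows = [
        {
            "thread_id": lb.thread_id,
            "position": lb.position,
            "sim_to_first": lb.score,
            "sim_to_prev": prev.get((lb.thread_id, lb.position), math.nan),
            "baseline": lb.baseline,
            "is_drift": lb.is_drift,
        }
        for lb in labels
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "thread_id", "position", "sim_to_first", "sim_to_prev",
            "baseline", "is_drift",
        ],
    )
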