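"""End-to-end wiring: corpus -> vectors -> trajectories -> detectors -> scores.

Thin conveniences shared by the command-line interface, the evaluation
harness and the acceptance studies; every step is a call into the
underlying modules.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .corpus import Corpus, filter_threads
from .counteraction import (
    CounteractionEvent,
    MemberRoleEffort,
    RoleSummary,
    TestResult,
    assign_roles,
    compare_roles,
    compute_effort,
    detect_counteractions,
    summarize_by_role,
)
from .drift import (
    DEFAULT_MIN_SUPPORT,
    PositionBaselineDriftClassifier,
    SimilarityTrajectory,
    trajectory,
)
from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics
from .synthgen import GoldLabels, events_from_labels
from .textvec import CommunityTfidf, fit_tfidf

__all__ = [
    "corpus_trajectories",
    "evaluate_drift_detection",
    "evaluate_counteraction_detection",
    "role_effort_study",
]


def corpus_trajectories(
    corpus: Corpus, model: CommunityTfidf | None = None, **tfidf_params
) -> tuple[CommunityTfidf, list[SimilarityTrajectory]]:
    """Fit (or reuse) the community tf-idf model and build one similarity
    trajectory per thread of length >= 2."""
    corpus = filter_threads(corpus)
    if model is None:
        model = fit_tfidf(corpus, **tfidf_params)
    trajectories = [trajectory(t, model) for t in corpus.threads]
    return model, trajectories


def evaluate_drift_detection(
    corpus: Corpus,
    gold: GoldLabels,
    min_support: int = DEFAULT_MIN_SUPPORT,
    margin: float = 0.0,
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Classify every baseline-covered reply of ``corpus`` and score the
    predictions against the gold drift labels."""
    _, trajectories = corpus_trajectories(corpus)
    clf = PositionBaselineDriftClassifier(min_support=min_support, margin=margin)
    clf.fit(trajectories)
    labels = clf.label_trajectories(trajectories, on_missing="skip")
    lookup = gold.lookup()
    predicted = [lb.is_drift for lb in labels]
    truth = [lookup[(lb.thread_id, lb.position)].is_drift for lb in labels]
    cm = confusion(predicted, truth)
    return cm, metrics(cm)


def evaluate_counteraction_detection(
    corpus: Corpus, gold: GoldLabels, epsilon: float = 0.0
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Score detected similarity increases against gold counteraction posts
    over all positions >= 3."""
    _, trajectories = corpus_trajectories(corpus)
    detected: set[tuple[str, int]] = set()
    eligible: list[tuple[str, int]] = []
    for traj in trajectories:
        for pt in traj.points:
            if pt.position >= 3:
                eligible.append((traj.thread_id, pt.position))
        for ev in detect_counteractions(traj, epsilon=epsilon):
            detected.add((ev.thread_id, ev.position))
    lookup = gold.lookup()
    predicted = [key in detected for key in eligible]
    truth = [lookup[key].is_counteraction for key in eligible]
    cm = confusion(predicted, truth)
    return cm, metrics(cm)


def role_effort_study(
    corpus: Corpus,
    gold: GoldLabels | None = None,
    epsilon: float = 0.0,
) -> tuple[list[MemberRoleEffort], list[RoleSummary], list[TestResult]]:
    """Per-member-role counteraction effort and the role-comparison tests.

    With ``gold`` the effort accounting uses the generative counteraction
    events (isolating the accounting and statistics from detector noise);
    otherwise events come from the similarity-increase detector.
    """
    corpus = filter_threads(corpus)
    if gold is not None:
        events: list[CounteractionEvent] = events_from_labels(gold)
    else:
        _, trajectories = corpus_trajectories(corpus)
        events = [
            ev
            for traj in trajectories
            for ev in detect_counteractions(traj, epsilon=epsilon)
        ]
    roles = assign_roles(corpus)
    efforts = compute_effort(corpus, events, roles)
    summaries = summarize_by_role(efforts)
    tests = compare_roles(efforts)
    return efforts, summaries, tests
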