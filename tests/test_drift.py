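from __future__ import annotations

import math

import numpy as np
import pytest
from sklearn.base import clone

from threaddrift.drift import (
    BaselineUndefinedError,
    PositionBaseline,
    PositionBaselineDriftClassifier,
    SimilarityTrajectory,
    TrajectoryPoint,
    classify_drift,
    fit_log_trend,
    labels_to_frame,
    position_baseline,
    trajectory,
)
from threaddrift.textvec import fit_tfidf

from _oracles import dense_cosine, dense_tfidf
from conftest import make_corpus, make_thread


def _traj(thread_id: str, sims: dict[int, float]) -> SimilarityTrajectory:
    return SimilarityTrajectory(
        thread_id=thread_id,
        points=tuple(
            TrajectoryPoint(position=p, sim_to_first=s, sim_to_prev=0.0)
            for p, s in sorted(sims.items())
        ),
    )


def _baseline(means: dict[int, float], min_support: int = 1) -> PositionBaseline:
    return PositionBaseline(
        means=means, counts={p: min_support for p in means}, min_support=min_support
    )


class TestTrajectory:
    def test_identical_bodies_stay_at_one(self):
        # extra thread supplies vocabulary contrast so idf is nonzero
        corpus = make_corpus([
            make_thread("t", ["echo result normal", "echo result normal",
                              "echo result normal"]),
            make_thread("u", ["totally different words here", "more new words"]),
        ])
        model = fit_tfidf(corpus)
        traj = trajectory(corpus.threads[0], model)
        assert [(p.position, p.sim_to_first, p.sim_to_prev) for p in traj.points] == [
            (2, pytest.approx(1.0), pytest.approx(1.0)),
            (3, pytest.approx(1.0), pytest.approx(1.0)),
        ]

    def test_permuted_bags_stay_at_one(self):
        corpus = make_corpus([
            make_thread("t", ["a b c", "c b a", "b a c"]),
            make_thread("u", ["x y", "z w"]),
        ])
        model = fit_tfidf(corpus)
        traj = trajectory(corpus.threads[0], model)
        assert all(p.sim_to_first == pytest.approx(1.0) for p in traj.points)

    def test_disjoint_reply_scores_zero(self):
        corpus = make_corpus([
            make_thread("t", ["heart rate question", "insurance claim denied"]),
        ])
        model = fit_tfidf(corpus)
        traj = trajectory(corpus.threads[0], model)
        assert traj.points[0].sim_to_first == 0.0

    def test_short_thread_rejected(self):
        corpus = make_corpus([make_thread("t", ["solo"])])
        model = fit_tfidf(corpus)
        with pytest.raises(ValueError):
            trajectory(corpus.threads[0], model)

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(42)
        alphabet = [f"w{i}" for i in range(30)]
        docs = [list(rng.choice(alphabet, size=8)) for _ in range(5)]
        corpus = make_corpus([make_thread("t", [" ".join(d) for d in docs])])
        model = fit_tfidf(corpus)
        traj = trajectory(corpus.threads[0], model)
        dense, _ = dense_tfidf(docs)
        for pt in traj.points:
            i = pt.position - 1
            assert pt.sim_to_first == pytest.approx(
                max(0.0, dense_cosine(dense[i], dense[0])), abs=1e-12
            )
            assert pt.sim_to_prev == pytest.approx(
                max(0.0, dense_cosine(dense[i], dense[i - 1])), abs=1e-12
            )


class TestPositionBaseline:
    def test_arithmetic_mean_per_position(self):
        trajs = [_traj("a", {2: 0.5, 3: 0.4}), _traj("b", {2: 0.3, 3: 0.2})]
        base = position_baseline(trajs, min_support=2)
        assert base.means == {2: pytest.approx(0.40), 3: pytest.approx(0.30)}
        assert base.counts == {2: 2, 3: 2}

    def test_min_support_filters_positions(self):
        trajs = [_traj("a", {2: 0.5, 3: 0.4}), _traj("b", {2: 0.3})]
        base = position_baseline(trajs, min_support=2)
        assert set(base.means) == {2}

    def test_unreachable_support_warns_and_is_empty(self):
        trajs = [_traj("a", {2: 0.5})]
        with pytest.warns(UserWarning, match="min_support"):
            base = position_baseline(trajs, min_support=3)
        assert base.means == {}

    def test_constant_scores_give_constant_baseline(self):
        trajs = [_traj(str(i), {2: 0.7, 3: 0.7, 4: 0.7}) for i in range(5)]
        base = position_baseline(trajs, min_support=5)
        assert all(m == pytest.approx(0.7) for m in base.means.values())


class TestClassifyDrift:
    def test_below_baseline_is_drift(self):
        label = classify_drift(
            TrajectoryPoint(2, 0.2, 0.0), _baseline({2: 0.4}), margin=0.0
        )
        assert label.is_drift is True

    def test_tie_is_not_drift(self):
        label = classify_drift(TrajectoryPoint(2, 0.4, 0.0), _baseline({2: 0.4}))
        assert label.is_drift is False

    def test_above_baseline_is_not_drift(self):
        label = classify_drift(TrajectoryPoint(2, 0.5, 0.0), _baseline({2: 0.4}))
        assert label.is_drift is False

    def test_margin_shifts_threshold_down(self):
        point = TrajectoryPoint(2, 0.35, 0.0)
        assert classify_drift(point, _baseline({2: 0.4}), margin=0.0).is_drift
        assert not classify_drift(point, _baseline({2: 0.4}), margin=0.1).is_drift

    def test_missing_position_raises_with_guidance(self):
        with pytest.raises(BaselineUndefinedError, match="min_support"):
            classify_drift(TrajectoryPoint(9, 0.5, 0.0), _baseline({2: 0.4}))

    def test_monotone_in_score(self):
        base = _baseline({2: 0.5})
        scores = np.linspace(0, 1, 21)
        flags = [
            classify_drift(TrajectoryPoint(2, s, 0.0), base).is_drift for s in scores
        ]
        # once a score stops being drift, no higher score may flip back
        assert flags == sorted(flags, reverse=True)


class TestLogTrend:
    def test_recovers_published_coefficients_from_noiseless_curve(self):
        positions = range(2, 31)
        means = {p: -0.017 * math.log(p) + 0.1296 for p in positions}
        base = _baseline(means)
        fit = fit_log_trend(base)
        assert fit.slope == pytest.approx(-0.017, abs=1e-10)
        assert fit.intercept == pytest.approx(0.1296, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_input_gives_zero_slope(self):
        base = _baseline({2: 0.3, 3: 0.3, 4: 0.3})
        fit = fit_log_trend(base)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.3)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_points_match_closed_form_ols(self):
        means = {2: 0.50, 3: 0.40, 5: 0.35}
        base = _baseline(means)
        x = np.log(np.array(sorted(means)))
        y = np.array([means[p] for p in sorted(means)])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        fit = fit_log_trend(base)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_log_trend(_baseline({2: 0.5, 3: 0.4}))


class TestClassifierEstimator:
    def _fitted(self):
        trajs = [
            _traj("a", {2: 0.6, 3: 0.5}),
            _traj("b", {2: 0.4, 3: 0.1}),
        ]
        clf = PositionBaselineDriftClassifier(min_support=2, margin=0.0)
        return clf.fit(trajs), trajs

    def test_predict_matches_rule(self):
        clf, _ = self._fitted()
        # baselines: pos2 -> 0.5, pos3 -> 0.3
        preds = clf.predict([(2, 0.45), (2, 0.55), (3, 0.3)])
        assert preds.tolist() == [True, False, False]

    def test_label_trajectories_skip_mode(self):
        clf, trajs = self._fitted()
        extra = _traj("c", {2: 0.2, 3: 0.2, 4: 0.9})
        labels = clf.label_trajectories(trajs + [extra], on_missing="skip")
        assert all(lb.position in (2, 3) for lb in labels)
        with pytest.raises(BaselineUndefinedError):
            clf.label_trajectories([extra], on_missing="error")

    def test_clone_preserves_params(self):
        clf = PositionBaselineDriftClassifier(min_support=7, margin=0.05)
        assert clone(clf).get_params() == clf.get_params()

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            PositionBaselineDriftClassifier().predict([(2, 0.5)])

    def test_export_frame_columns(self):
        clf, trajs = self._fitted()
        labels = clf.label_trajectories(trajs)
        frame = labels_to_frame(labels, trajs)
        assert list(frame.columns) == [
            "thread_id", "position", "sim_to_first", "sim_to_prev",
            "baseline", "is_drift",
        ]
        assert len(frame) == 4
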