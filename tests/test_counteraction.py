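from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from threaddrift.counteraction import (
    CounteractionEvent,
    MemberRoleEffort,
    Role,
    _mannwhitney,
    assign_roles,
    compare_roles,
    compute_effort,
    detect_counteractions,
    holm_bonferroni,
    member_means,
    rank_biserial,
    summarize_by_role,
)
from threaddrift.drift import SimilarityTrajectory, TrajectoryPoint

from conftest import make_corpus, make_thread


def _traj(sims: dict[int, float], thread_id: str = "t") -> SimilarityTrajectory:
    return SimilarityTrajectory(
        thread_id=thread_id,
        points=tuple(
            TrajectoryPoint(position=p, sim_to_first=s, sim_to_prev=0.0)
            for p, s in sorted(sims.items())
        ),
    )


def _effort(author: str, role: Role, thread: str, replies: int, counter: int):
    return MemberRoleEffort(
        author_id=author,
        role=role,
        thread_id=thread,
        n_replies=replies,
        n_counteractions=counter,
    )


class TestDetect:
    def test_increase_detected_at_position_four(self):
        events = detect_counteractions(_traj({2: 0.5, 3: 0.2, 4: 0.4}))
        assert len(events) == 1
        assert events[0].position == 4
        assert events[0].delta == pytest.approx(0.2)

    def test_natural_drift_yields_no_events(self):
        assert detect_counteractions(_traj({2: 0.5, 3: 0.4, 4: 0.3})) == []

    def test_epsilon_threshold_suppresses_small_increases(self):
        assert detect_counteractions(_traj({2: 0.5, 3: 0.2, 4: 0.4}), epsilon=0.25) == []

    def test_two_post_thread_has_no_eligible_positions(self):
        assert detect_counteractions(_traj({2: 0.9})) == []

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            detect_counteractions(_traj({2: 0.5}), epsilon=-0.1)


def _role_corpus():
    """Moderators with 10 and 20 posts (mean 15), a power user with 16,
    a regular user with 3, and an original poster."""
    pad_authors = ["m1"] * 10 + ["m2"] * 20 + ["pw"] * 15 + ["reg"] * 2
    pad_roles = ["staff"] * 10 + ["md"] * 20 + ["user"] * 17
    pad = make_thread(
        "pad", [f"body {i}" for i in range(len(pad_authors))],
        authors=pad_authors, roles=pad_roles,
    )
    t = make_thread(
        "T", ["question", "answer one", "answer two"],
        authors=["op1", "pw", "reg"],
    )
    return make_corpus([pad, t], moderators={"m1", "m2"})


class TestRoles:
    def test_role_assignment_rules(self):
        roles = assign_roles(_role_corpus())
        assert roles[("T", "op1")] is Role.ORIGINAL_POSTER
        assert roles[("T", "pw")] is Role.POWER_USER  # 16 > mean moderator 15
        assert roles[("T", "reg")] is Role.REGULAR_USER  # 3 posts
        assert roles[("pad", "m2")] is Role.STAFF_MD

    def test_moderator_precedence_over_original_poster(self):
        roles = assign_roles(_role_corpus())
        # m1 initiated the pad thread but stays staff/md
        assert roles[("pad", "m1")] is Role.STAFF_MD

    def test_threshold_tie_resolves_to_regular(self):
        corpus = _role_corpus()
        # pw has 16 posts vs threshold 15 (power); a member with exactly 15 is not
        pad_authors = ["m1"] * 10 + ["m2"] * 20 + ["tie"] * 14
        pad = make_thread(
            "pad", [f"b{i}" for i in range(44)],
            authors=pad_authors, roles=["staff"] * 10 + ["md"] * 20 + ["user"] * 14,
        )
        t = make_thread("T", ["q", "a"], authors=["op1", "tie"])
        corpus = make_corpus([pad, t], moderators={"m1", "m2"})
        assert assign_roles(corpus)[("T", "tie")] is Role.REGULAR_USER

    def test_without_moderators_power_tier_disabled(self):
        big = make_thread("big", [f"b{i}" for i in range(30)],
                          authors=["op"] + ["busy"] * 29)
        with pytest.warns(UserWarning, match="power-user tier is disabled"):
            roles = assign_roles(make_corpus([big]))
        assert roles[("big", "busy")] is Role.REGULAR_USER


class TestEffort:
    def _corpus(self):
        t = make_thread(
            "E", ["q", "r1", "r2", "r3", "r4"],
            authors=["o", "x", "x", "x", "x"],
        )
        return make_corpus([t])

    def test_half_of_replies_credited(self):
        corpus = self._corpus()
        events = [CounteractionEvent("E", 3, 0.2), CounteractionEvent("E", 5, 0.1)]
        roles = assign_roles(corpus)
        (record,) = compute_effort(corpus, events, roles)
        assert record.author_id == "x"
        assert record.n_replies == 4
        assert record.n_counteractions == 2
        assert record.effort == pytest.approx(0.5)

    def test_op_without_replies_has_no_record(self):
        corpus = self._corpus()
        records = compute_effort(corpus, [], assign_roles(corpus))
        assert {r.author_id for r in records} == {"x"}

    def test_every_reply_counteracting_gives_effort_one(self):
        corpus = self._corpus()
        events = [CounteractionEvent("E", p, 0.1) for p in (2, 3, 4, 5)]
        (record,) = compute_effort(corpus, events, assign_roles(corpus))
        assert record.effort == 1.0


class TestSummaries:
    def test_role_mean_over_members(self):
        efforts = [
            _effort("a", Role.REGULAR_USER, "t1", 5, 2),  # 0.4
            _effort("b", Role.REGULAR_USER, "t2", 5, 3),  # 0.6
        ]
        (summary,) = summarize_by_role(efforts)
        assert summary.mean == pytest.approx(0.5)
        assert summary.n == 2
        assert summary.ci_low <= summary.mean <= summary.ci_high

    def test_two_stage_averaging_weights_members_equally(self):
        efforts = [
            _effort("a", Role.REGULAR_USER, "t1", 10, 2),  # member a: .2
            _effort("a", Role.REGULAR_USER, "t2", 10, 4),  # and .4 -> mean .3
            _effort("b", Role.REGULAR_USER, "t3", 10, 8),  # member b: .8
        ]
        grouped = member_means(efforts)
        assert sorted(grouped[Role.REGULAR_USER]) == pytest.approx([0.3, 0.8])
        (summary,) = summarize_by_role(efforts)
        assert summary.mean == pytest.approx(0.55)

    def test_identical_efforts_have_zero_sd(self):
        efforts = [
            _effort(m, Role.POWER_USER, "t", 4, 2) for m in ("a", "b", "c")
        ]
        (summary,) = summarize_by_role(efforts)
        assert summary.sd == 0.0
        assert summary.ci_low == summary.ci_high == summary.mean


class TestStatistics:
    def test_complete_separation_gives_r_one(self):
        efforts = [
            _effort(f"a{i}", Role.REGULAR_USER, "t", 10, c) for i, c in enumerate((1, 2, 3))
        ] + [
            _effort(f"b{i}", Role.ORIGINAL_POSTER, "t", 10, c)
            for i, c in enumerate((4, 5, 6))
        ]
        results = compare_roles(efforts)
        pair = next(r for r in results if r.test == "mann_whitney")
        # pairs are ordered alphabetically: original_poster first, with the
        # larger efforts, so U = n1*n2 and r = -1 (complete separation)
        assert pair.groups == ("original_poster", "regular_user")
        assert abs(pair.effect_size) == pytest.approx(1.0)
        assert pair.adjusted_p >= pair.raw_p

    def test_identical_groups_have_zero_h(self):
        efforts = [
            _effort("a", Role.REGULAR_USER, "t", 10, 2),
            _effort("b", Role.REGULAR_USER, "t", 10, 4),
            _effort("c", Role.POWER_USER, "t", 10, 2),
            _effort("d", Role.POWER_USER, "t", 10, 4),
        ]
        kw = compare_roles(efforts)[0]
        assert kw.test == "kruskal_wallis"
        assert kw.statistic == pytest.approx(0.0)

    def test_single_member_roles_are_dropped_with_warning(self):
        efforts = [
            _effort("a", Role.REGULAR_USER, "t", 10, 1),
            _effort("b", Role.REGULAR_USER, "t", 10, 2),
            _effort("lone", Role.STAFF_MD, "t", 10, 5),
        ]
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError, match=">= 2 roles"):
                compare_roles(efforts)

    def test_holm_bonferroni_worked_example(self):
        assert holm_bonferroni([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_holm_is_monotone_and_dominates_raw(self):
        raw = [0.001, 0.04, 0.012, 0.8, 0.03]
        adj = holm_bonferroni(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        order = np.argsort(raw)
        assert sorted(np.array(adj)[order].tolist()) == np.array(adj)[order].tolist()

    def test_rank_biserial_closed_form(self):
        assert rank_biserial(0, 3, 3) == 1.0
        assert rank_biserial(9, 3, 3) == -1.0
        assert rank_biserial(4.5, 3, 3) == 0.0

    def test_identical_samples_give_zero_r(self):
        u, _ = _mannwhitney([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert rank_biserial(u, 3, 3) == 0.0

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=15),
        st.lists(st.integers(0, 5), min_size=2, max_size=15),
    )
    def test_u_statistics_sum_to_n1_n2(self, xs, ys):
        u1, _ = _mannwhitney(xs, ys)
        u2, _ = _mannwhitney(ys, xs)
        assert u1 + u2 == pytest.approx(len(xs) * len(ys))
        assert -1.0 <= rank_biserial(u1, len(xs), len(ys)) <= 1.0
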