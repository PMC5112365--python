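"""Counteraction detection, member roles, effort accounting and statistics.

A counteraction is an irregular *increase* of similarity-to-first-post:
post p is more relevant to the original post than post p-1 was,
suggesting someone steered the thread back on topic.  Effort is the
share of a member's replies in a thread that counteract; members act in
mutually exclusive roles per thread (staff/MD moderator, original
poster, power user, regular user) and role averages are compared with
nonparametric tests (Kruskal-Wallis across roles, pairwise Mann-Whitney
with Holm-Bonferroni correction and rank-biserial effect sizes).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus
from .drift import SimilarityTrajectory

__all__ = [
    "Role",
    "CounteractionEvent",
    "MemberRoleEffort",
    "RoleSummary",
    "TestResult",
    "detect_counteractions",
    "assign_roles",
    "compute_effort",
    "member_means",
    "summarize_by_role",
    "compare_roles",
    "rank_biserial",
    "holm_bonferroni",
    "efforts_to_frame",
]


class Role(str, enum.Enum):
    ORIGINAL_POSTER = "original_poster"
    STAFF_MD = "staff_md"
    POWER_USER = "power_user"
    REGULAR_USER = "regular_user"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CounteractionEvent:
    """Similarity-to-first increased at ``position`` by ``delta`` (> epsilon)."""

    thread_id: str
    position: int
    delta: float


@dataclass(frozen=True)
class MemberRoleEffort:
    """One member's counteraction effort within one thread."""

    author_id: str
    role: Role
    thread_id: str
    n_replies: int
    n_counteractions: int

    @property
    def effort(self) -> float:
        return self.n_counteractions / self.n_replies


@dataclass(frozen=True)
class RoleSummary:
    role: Role
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TestResult:
    test: str  # "kruskal_wallis" | "mann_whitney"
    groups: tuple[str, ...]
    statistic: float
    raw_p: float
    adjusted_p: float | None = None
    effect_size: float | None = None
    mean_difference: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def detect_counteractions(
    traj: SimilarityTrajectory, epsilon: float = 0.0
) -> list[CounteractionEvent]:
    """Events at positions p >= 3 where sim_to_first rose by more than epsilon."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    sims = traj.sim_to_first()
    events = []
    for pt in traj.points:
        prev = sims.get(pt.position - 1)
        if prev is None:  # position 2 has no reply predecessor
            continue
        delta = pt.sim_to_first - prev
        if delta > epsilon:
            events.append(
                CounteractionEvent(
                    thread_id=traj.thread_id, position=pt.position, delta=delta
                )
            )
    return events


def assign_roles(corpus: Corpus) -> dict[tuple[str, str], Role]:
    """Mutually exclusive per-thread roles for every posting member.

    Precedence: staff/MD (by moderator id) > original poster (own thread)
    > power user (community post count strictly above the moderators'
    average post count) > regular user.  With zero moderators the power
    tier is undefined and disabled with a warning.
    """
    post_counts: dict[str, int] = {}
    for post in corpus.posts():
        post_counts[post.author_id] = post_counts.get(post.author_id, 0) + 1

    moderators = set(corpus.moderator_ids)
    if moderators:
        mod_posts = sum(post_counts.get(m, 0) for m in moderators)
        power_threshold = mod_posts / len(moderators)
    else:
        warnings.warn(
            f"community {corpus.community_id!r} has no moderators; the "
            "power-user tier is disabled (threshold undefined)",
            stacklevel=2,
        )
        power_threshold = math.inf

    roles: dict[tuple[str, str], Role] = {}
    for thread in corpus.threads:
        op = thread.original_post.author_id
        for post in thread.posts:
            key = (thread.thread_id, post.author_id)
            if key in roles:
                continue
            if post.author_id in moderators:
                roles[key] = Role.STAFF_MD
            elif post.author_id == op:
                roles[key] = Role.ORIGINAL_POSTER
            elif post_counts[post.author_id] > power_threshold:
                roles[key] = Role.POWER_USER
            else:
                roles[key] = Role.REGULAR_USER
    return roles


def compute_effort(
    corpus: Corpus,
    events: Iterable[CounteractionEvent],
    roles: Mapping[tuple[str, str], Role],
) -> list[MemberRoleEffort]:
    """Per-(member, thread) counteraction effort.

    A counteraction is credited to the author of the post at the event's
    position.  ``n_replies`` excludes the original post, so an OP who
    never replies to their own thread yields no record there.
    """
    event_positions: dict[str, set[int]] = {}
    for ev in events:
        event_positions.setdefault(ev.thread_id, set()).add(ev.position)

    records = []
    for thread in corpus.threads:
        positions = event_positions.get(thread.thread_id, set())
        replies: dict[str, int] = {}
        credited: dict[str, int] = {}
        for post in thread.replies:
            replies[post.author_id] = replies.get(post.author_id, 0) + 1
            if post.position in positions:
                credited[post.author_id] = credited.get(post.author_id, 0) + 1
        for author, n_replies in replies.items():
            records.append(
                MemberRoleEffort(
                    author_id=author,
                    role=roles[(thread.thread_id, author)],
                    thread_id=thread.thread_id,
                    n_replies=n_replies,
                    n_counteractions=credited.get(author, 0),
                )
            )
    return records


def member_means(efforts: Iterable[MemberRoleEffort]) -> dict[Role, list[float]]:
    """First averaging stage: each member's mean per-thread effort within a
    role; returns the member means grouped by role."""
    per_member: dict[tuple[Role, str], list[float]] = {}
    for rec in efforts:
        per_member.setdefault((rec.role, rec.author_id), []).append(rec.effort)
    grouped: dict[Role, list[float]] = {}
    for (role, _author), values in sorted(per_member.items()):
        grouped.setdefault(role, []).append(sum(values) / len(values))
    return grouped


def summarize_by_role(efforts: Iterable[MemberRoleEffort]) -> list[RoleSummary]:
    """Two-stage role averages with SD and a normal-approximation 95% CI
    over member means (mean +/- 1.96*SD/sqrt(n))."""
    summaries = []
    for role, values in member_means(efforts).items():
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        half = 1.96 * sd / math.sqrt(arr.size)
        summaries.append(
            RoleSummary(
                role=role,
                n=arr.size,
                mean=mean,
                sd=sd,
                ci_low=mean - half,
                ci_high=mean + half,
            )
        )
    summaries.sort(key=lambda s: s.role.value)
    return summaries


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n1*n2), with U the Mann-Whitney
    statistic of the first group."""
    return 1.0 - 2.0 * u / (n1 * n2)


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values."""
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="holm")
    return [float(p) for p in adjusted]


def _mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic of the first group).

    Exact null for small tie-free samples, normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_roles(
    efforts: Iterable[MemberRoleEffort], min_group: int = 2
) -> list[TestResult]:
    """Kruskal-Wallis over all roles plus Holm-corrected pairwise
    Mann-Whitney tests on member-mean efforts.

    Returns the omnibus test first, then one result per role pair with the
    rank-biserial effect size, the difference of member-mean efforts
    (second minus first) and its normal-approximation 95% CI.
    """
    grouped = member_means(efforts)
    usable = {
        role: np.asarray(vals, dtype=float)
        for role, vals in grouped.items()
        if len(vals) >= min_group
    }
    dropped = set(grouped) - set(usable)
    if dropped:
        warnings.warn(
            f"roles excluded from comparison (fewer than {min_group} member "
            f"observations): {sorted(r.value for r in dropped)}",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need >= 2 roles with enough observations to compare")

    roles = sorted(usable, key=lambda r: r.value)
    samples = [usable[r] for r in roles]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h_stat, h_p = 0.0, 1.0
    else:
        h_stat, h_p = stats.kruskal(*samples)
    results = [
        TestResult(
            test="kruskal_wallis",
            groups=tuple(r.value for r in roles),
            statistic=float(h_stat),
            raw_p=float(h_p),
        )
    ]

    pairs = [
        (roles[i], roles[j])
        for i in range(len(roles))
        for j in range(i + 1, len(roles))
    ]
    raw = []
    for a, b in pairs:
        u, p = _mannwhitney(usable[a], usable[b])
        raw.append((a, b, u, p))
    adjusted = holm_bonferroni([p for *_, p in raw])
    for (a, b, u, p), adj in zip(raw, adjusted):
        xa, xb = usable[a], usable[b]
        diff = float(xb.mean() - xa.mean())
        se = math.sqrt(
            (xa.var(ddof=1) if xa.size > 1 else 0.0) / xa.size
            + (xb.var(ddof=1) if xb.size > 1 else 0.0) / xb.size
        )
        results.append(
            TestResult(
                test="mann_whitney",
                groups=(a.value, b.value),
                statistic=u,
                raw_p=p,
                adjusted_p=adj,
                effect_size=rank_biserial(u, xa.size, xb.size),
                mean_difference=diff,
                ci_low=diff - 1.96 * se,
                ci_high=diff + 1.96 * se,
            )
        )
    return results


def efforts_to_frame(efforts: Iterable[MemberRoleEffort]) -> pd.DataFrame:
    rows = [
        {
            "author_id": e.author_id,
            "role": e.role.value,
            "thread_id": e.thread_id,
            "n_replies": e.n_replies,
            "n_counteractions": e.n_counteractions,
            "effort": e.effort,
        }
        for e in efforts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "author_id", "role", "thread_id", "n_replies",
            "n_counteractions", "effort",
        ],
    )
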