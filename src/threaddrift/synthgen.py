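"""Seeded generator of synthetic threaded corpora with ground truth.

The generator emulates the statistical structure the drift analysis
assumes, not natural language.  Each community owns a set of topics,
each topic a vocabulary (disjoint across topics up to a configurable
overlap fraction).  A thread starts from a small mixture of topics
(about three, echoing what threaded health discussions open with) and
evolves post by post:

* gradual drift — a fixed fraction (1 - carryover) of the topic-mixture
  mass moves to a fresh topic at every step, so the mass remaining on
  the original topics after k steps is exactly carryover**k;
* abrupt drift — with some probability per post the whole mixture is
  replaced by fresh topics (a "hijack"), which zeroes the original mass;
* counteraction — once the conversation has noticeably drifted (original
  mass below an opportunity threshold), a reply may restore the original
  post's topic mixture, with a probability that depends on the author's
  role in the thread.

Post bodies are bags of words sampled from the active mixture; post
length is drawn per post (lognormal) to exercise the length invariance
of cosine similarity.  Member activity is heavy-tailed (Zipf), which is
what makes the power-user tier non-empty, and a small set of moderator
ids posts at a constant rate.

Every post carries gold labels: ``is_drift`` (the thread is in an
abrupt-replacement state at that post), ``is_counteraction`` (the post
restored the original mixture), the author's per-thread role, and the
original-topic mass its body was sampled from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus import Corpus, Post, Thread
from .counteraction import CounteractionEvent, Role

__all__ = [
    "SynthConfig",
    "PostLabel",
    "GoldLabels",
    "generate_corpus",
    "generate",
    "expected_trajectory",
    "events_from_labels",
    "write_labels",
]

_EPS_PRUNE = 1e-3  # mixture weights below this are dropped and renormalized


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic forum corpus.

    Defaults follow the threaded-health-forum structure the analysis
    targets: threads of 2-99 posts averaging about 6.8, roughly three
    topics per original post, strong per-step topic carryover with
    occasional abrupt hijacks, role-dependent counteraction propensity
    ordered original poster > power user > staff > regular user, a dozen
    moderators per community and Zipf-distributed member activity.
    """

    n_communities: int = 1
    n_threads: int = 500
    thread_length_min: int = 2
    thread_length_max: int = 99
    thread_length_mean: float = 6.76
    n_topics: int = 100
    vocab_per_topic: int = 10
    overlap: float = 0.0
    words_per_post_median: float = 150.0
    words_per_post_sigma: float = 0.3
    topics_per_post_mean: float = 3.44
    carryover: float = 0.9
    abrupt_drift: float = 0.15
    counteraction_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "original_poster": 0.6,
            "staff_md": 0.45,
            "power_user": 0.5,
            "regular_user": 0.1,
        }
    )
    opportunity_threshold: float = 1.0 / 3.0
    dominant_drift: bool = False
    hijack_position: int | None = None
    n_moderators: int = 12
    member_pool: int | None = None
    zipf_a: float = 1.5
    p_op_reply: float = 0.3
    p_mod_reply: float = 0.05
    ot_title_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("overlap", "carryover", "abrupt_drift", "p_op_reply",
                     "p_mod_reply", "ot_title_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for role, p in self.counteraction_probs.items():
            if role not in {r.value for r in Role}:
                raise ValueError(f"unknown role in counteraction_probs: {role!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"counteraction_probs[{role!r}] must be in [0, 1]")
        if self.thread_length_min < 2 or self.thread_length_max < self.thread_length_min:
            raise ValueError("need 2 <= thread_length_min <= thread_length_max")
        if not self.thread_length_min <= self.thread_length_mean <= self.thread_length_max:
            raise ValueError("thread_length_mean must lie within [min, max]")
        if self.n_topics < 2 * math.ceil(self.topics_per_post_mean):
            raise ValueError(
                "infeasible config: n_topics must be at least twice the mean "
                "topics per post so abrupt drift can draw fresh topics"
            )
        if self.p_op_reply + self.p_mod_reply > 1.0:
            raise ValueError("p_op_reply + p_mod_reply must be <= 1")
        if self.n_moderators < 0 or self.n_threads < 1 or self.n_communities < 1:
            raise ValueError("n_moderators >= 0, n_threads >= 1, n_communities >= 1")
        if self.vocab_per_topic < 1:
            raise ValueError("vocab_per_topic must be >= 1")


@dataclass(frozen=True)
class PostLabel:
    thread_id: str
    position: int
    author_id: str
    role: Role
    is_drift: bool
    is_counteraction: bool
    frac_original: float


@dataclass(frozen=True)
class GoldLabels:
    """Per-post generative ground truth, keyed by (thread_id, position)."""

    posts: tuple[PostLabel, ...]

    def __iter__(self):
        return iter(self.posts)

    def lookup(self) -> dict[tuple[str, int], PostLabel]:
        return {(lb.thread_id, lb.position): lb for lb in self.posts}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "thread_id": lb.thread_id,
                    "position": lb.position,
                    "author_id": lb.author_id,
                    "role": lb.role.value,
                    "is_drift": lb.is_drift,
                    "is_counteraction": lb.is_counteraction,
                    "frac_original": lb.frac_original,
                }
                for lb in self.posts
            ],
            columns=[
                "thread_id", "position", "author_id", "role",
                "is_drift", "is_counteraction", "frac_original",
            ],
        )


def _topic_vocab(rng: np.random.Generator, ci: int, cfg: SynthConfig) -> list[list[str]]:
    """Per-topic word lists; an ``overlap`` fraction of each topic's words is
    drawn from a community-wide shared pool (overlap 1 kills the signal)."""
    v = cfg.vocab_per_topic
    n_shared = int(round(cfg.overlap * v))
    shared_pool = [f"c{ci}s{j}" for j in range(v)]
    vocab = []
    for t in range(cfg.n_topics):
        own = [f"c{ci}t{t}w{j}" for j in range(v - n_shared)]
        if n_shared:
            borrowed = list(rng.choice(shared_pool, size=n_shared, replace=False))
            vocab.append(own + borrowed)
        else:
            vocab.append(own)
    return vocab


def _draw_length(rng: np.random.Generator, cfg: SynthConfig) -> int:
    extra_mean = cfg.thread_length_mean - cfg.thread_length_min + 1.0
    length = cfg.thread_length_min + int(rng.geometric(1.0 / extra_mean)) - 1
    return min(length, cfg.thread_length_max)


def _draw_n_topics(rng: np.random.Generator, cfg: SynthConfig) -> int:
    """Topic-set size: floor(mean) or ceil(mean), hitting the mean exactly.

    A narrow spread keeps threads comparable within a position, which is
    what the positional-baseline detector assumes; wide spreads in the
    number of active topics shift whole-thread similarity levels and
    would confound position effects with thread verbosity.
    """
    lo = math.floor(cfg.topics_per_post_mean)
    frac = cfg.topics_per_post_mean - lo
    k = lo + (1 if rng.random() < frac else 0)
    return max(1, min(k, cfg.n_topics // 2))


def _zipf_member(rng: np.random.Generator, pool: int, a: float) -> int:
    return min(int(rng.zipf(a)), pool) - 1


@dataclass
class _Mixture:
    weights: dict[int, float]

    def original_mass(self, originals: frozenset[int]) -> float:
        return sum(w for t, w in self.weights.items() if t in originals)

    def copy(self) -> "_Mixture":
        return _Mixture(dict(self.weights))


def _prune(weights: dict[int, float]) -> dict[int, float]:
    kept = {t: w for t, w in weights.items() if w >= _EPS_PRUNE}
    total = sum(kept.values())
    return {t: w / total for t, w in kept.items()}


class _TopicPool:
    """Hands out fresh topics, recycling inactive non-original ones when the
    community's topic inventory runs out."""

    def __init__(self, rng: np.random.Generator, n_topics: int, originals: frozenset[int]):
        self.rng = rng
        self.n_topics = n_topics
        self.originals = originals
        order = [t for t in rng.permutation(n_topics) if t not in originals]
        self.unused = [int(t) for t in order]

    def fresh(self, active: Iterable[int]) -> int:
        if self.unused:
            return self.unused.pop()
        active = set(active)
        candidates = [
            t for t in range(self.n_topics)
            if t not in self.originals and t not in active
        ]
        return int(self.rng.choice(candidates))


def _sample_body(
    rng: np.random.Generator,
    mixture: _Mixture,
    vocab: list[list[str]],
    cfg: SynthConfig,
    length_scale: float = 1.0,
) -> str:
    # Posts spanning more topics run proportionally longer (length_scale),
    # keeping the words-per-active-term sampling density comparable
    # across threads.
    w = int(
        np.clip(
            rng.lognormal(
                math.log(cfg.words_per_post_median * length_scale),
                cfg.words_per_post_sigma,
            ),
            5,
            600,
        )
    )
    topics = list(mixture.weights)
    probs = np.asarray([mixture.weights[t] for t in topics], dtype=float)
    probs = probs / probs.sum()
    topic_idx = rng.choice(len(topics), size=w, p=probs)
    words = [
        vocab[topics[i]][int(rng.integers(len(vocab[topics[i]])))] for i in topic_idx
    ]
    return " ".join(words)


def _generate_community(
    ci: int, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[Corpus, list[PostLabel]]:
    pool = cfg.member_pool or max(2 * cfg.n_threads, 10)
    moderators = [f"c{ci}mod{i}" for i in range(cfg.n_moderators)]
    mod_tags = {m: ("md" if i % 4 == 0 else "staff") for i, m in enumerate(moderators)}
    members = [f"c{ci}m{i}" for i in range(pool)]
    vocab = _topic_vocab(rng, ci, cfg)

    # Pass A: thread lengths and authorship, so per-thread roles are known
    # before any content (counteraction propensity depends on the role).
    plan: list[tuple[str, list[str]]] = []
    for n in range(cfg.n_threads):
        tid = f"c{ci}t{n}"
        length = _draw_length(rng, cfg)
        op = members[_zipf_member(rng, pool, cfg.zipf_a)]
        authors = [op]
        for position in range(2, length + 1):
            if cfg.hijack_position == position:
                authors.append(members[int(rng.integers(pool))])
                continue
            u = rng.random()
            if u < cfg.p_op_reply:
                authors.append(op)
            elif u < cfg.p_op_reply + cfg.p_mod_reply and moderators:
                authors.append(moderators[int(rng.integers(len(moderators)))])
            else:
                authors.append(members[_zipf_member(rng, pool, cfg.zipf_a)])
        plan.append((tid, authors))

    post_counts: dict[str, int] = {}
    for _, authors in plan:
        for a in authors:
            post_counts[a] = post_counts.get(a, 0) + 1
    mod_posts = sum(post_counts.get(m, 0) for m in moderators)
    power_threshold = mod_posts / len(moderators) if moderators else math.inf

    def role_of(author: str, op: str) -> Role:
        if author in mod_tags:
            return Role.STAFF_MD
        if author == op:
            return Role.ORIGINAL_POSTER
        if post_counts[author] > power_threshold:
            return Role.POWER_USER
        return Role.REGULAR_USER

    # Pass B: topic-state evolution and word sampling.
    threads: list[Thread] = []
    labels: list[PostLabel] = []
    for tid, authors in plan:
        op = authors[0]
        k = _draw_n_topics(rng, cfg)
        originals = frozenset(
            int(t) for t in rng.choice(cfg.n_topics, size=k, replace=False)
        )
        topic_pool = _TopicPool(rng, cfg.n_topics, originals)
        original_mix = _Mixture({t: 1.0 / k for t in originals})
        state = original_mix.copy()
        drifted = False

        def scale(mix: _Mixture) -> float:
            return max(len(mix.weights), 1) / cfg.topics_per_post_mean

        posts: list[Post] = []
        body = _sample_body(rng, original_mix, vocab, cfg, scale(original_mix))
        first_words = body.split()[:3]
        if rng.random() < cfg.ot_title_prob:
            title = "OT: " + " ".join(first_words)
        else:
            title = " ".join(first_words)
        posts.append(
            Post(
                community_id=f"c{ci}",
                thread_id=tid,
                position=1,
                author_id=op,
                role_tag=mod_tags.get(op, "user"),
                body=body,
                title=title,
            )
        )
        labels.append(
            PostLabel(
                thread_id=tid,
                position=1,
                author_id=op,
                role=role_of(op, op),
                is_drift=False,
                is_counteraction=False,
                frac_original=1.0,
            )
        )

        for position, author in zip(range(2, len(authors) + 1), authors[1:]):
            role = role_of(author, op)
            mass = state.original_mass(originals)
            forced_hijack = cfg.hijack_position == position
            counteracts = (
                not forced_hijack
                and position >= 3
                and mass < cfg.opportunity_threshold
                and rng.random() < cfg.counteraction_probs.get(role.value, 0.0)
            )
            if counteracts:
                display = original_mix.copy()
                if not cfg.dominant_drift:
                    state = original_mix.copy()
                    drifted = False
                is_drift = False
            else:
                if forced_hijack or rng.random() < cfg.abrupt_drift:
                    k_new = _draw_n_topics(rng, cfg)
                    fresh = [
                        topic_pool.fresh(state.weights) for _ in range(k_new)
                    ]
                    state = _Mixture({t: 1.0 / len(fresh) for t in set(fresh)})
                    drifted = True
                else:
                    decayed = {
                        t: w * cfg.carryover for t, w in state.weights.items()
                    }
                    fresh_topic = topic_pool.fresh(decayed)
                    decayed[fresh_topic] = (
                        decayed.get(fresh_topic, 0.0) + 1.0 - cfg.carryover
                    )
                    state = _Mixture(_prune(decayed))
                display = state
                is_drift = drifted

            posts.append(
                Post(
                    community_id=f"c{ci}",
                    thread_id=tid,
                    position=position,
                    author_id=author,
                    role_tag=mod_tags.get(author, "user"),
                    body=_sample_body(rng, display, vocab, cfg, scale(display)),
                )
            )
            labels.append(
                PostLabel(
                    thread_id=tid,
                    position=position,
                    author_id=author,
                    role=role,
                    is_drift=is_drift,
                    is_counteraction=counteracts,
                    frac_original=display.original_mass(originals),
                )
            )
        threads.append(Thread(thread_id=tid, posts=tuple(posts)))

    corpus = Corpus(
        community_id=f"c{ci}",
        threads=tuple(threads),
        moderator_ids=frozenset(moderators),
    )
    return corpus, labels


def generate(
    config: SynthConfig, seed: int | None = None
) -> tuple[list[Corpus], GoldLabels]:
    """Generate all communities of a synthetic corpus plus gold labels.

    Deterministic given the seed (``config.seed`` unless overridden).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    corpora = []
    labels: list[PostLabel] = []
    for ci in range(config.n_communities):
        corpus, community_labels = _generate_community(ci, config, rng)
        corpora.append(corpus)
        labels.extend(community_labels)
    return corpora, GoldLabels(posts=tuple(labels))


def generate_corpus(
    config: SynthConfig, seed: int | None = None
) -> tuple[Corpus | list[Corpus], GoldLabels]:
    """Like :func:`generate`, returning a bare Corpus when there is a single
    community (the common analysis unit)."""
    corpora, labels = generate(config, seed=seed)
    if config.n_communities == 1:
        return corpora[0], labels
    return corpora, labels


def expected_trajectory(
    config: SynthConfig, max_position: int = 20
) -> dict[int, float]:
    """Closed-form expected original-topic mass per position.

    Valid only for disjoint topic vocabularies and no abrupt events: the
    gradual process moves a (1 - carryover) fraction of mixture mass away
    per step, so after the p - 1 steps separating post p from the original
    post the original mass is carryover**(p-1) exactly.  Cosine similarity
    to the first post is a monotone transform of this mass and coincides
    with it at the extremes (0 and 1).
    """
    if config.overlap > 0:
        raise ValueError(
            "expected_trajectory has no closed form with overlapping "
            "topic vocabularies"
        )
    if config.abrupt_drift > 0:
        raise ValueError("expected_trajectory requires abrupt_drift == 0")
    return {p: config.carryover ** (p - 1) for p in range(2, max_position + 1)}


def events_from_labels(labels: GoldLabels) -> list[CounteractionEvent]:
    """Gold counteraction posts as events (for effort accounting that should
    not depend on detector noise)."""
    return [
        CounteractionEvent(thread_id=lb.thread_id, position=lb.position, delta=1.0)
        for lb in labels
        if lb.is_counteraction
    ]


def write_labels(labels: GoldLabels, path: str | Path) -> None:
    # %.17g round-trips doubles exactly
    labels.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_labels(path: str | Path) -> GoldLabels:
    frame = pd.read_csv(path, float_precision="round_trip")
    posts = tuple(
        PostLabel(
            thread_id=str(row.thread_id),
            position=int(row.position),
            author_id=str(row.author_id),
            role=Role(row.role),
            is_drift=bool(row.is_drift),
            is_counteraction=bool(row.is_counteraction),
            frac_original=float(row.frac_original),
        )
        for row in frame.itertuples()
    )
    return GoldLabels(posts=posts)
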