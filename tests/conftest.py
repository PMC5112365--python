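from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from threaddrift.corpus import Corpus, Post, Thread

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_post(
    thread_id: str,
    position: int,
    body: str,
    author: str = "alice",
    community: str = "heart",
    role: str = "user",
    title: str | None = None,
) -> Post:
    return Post(
        community_id=community,
        thread_id=thread_id,
        position=position,
        author_id=author,
        role_tag=role,
        body=body,
        title=title,
    )


def make_thread(thread_id: str, bodies: list[str], authors: list[str] | None = None,
                community: str = "heart", roles: list[str] | None = None) -> Thread:
    authors = authors or ["alice"] * len(bodies)
    roles = roles or ["user"] * len(bodies)
    posts = tuple(
        make_post(thread_id, i + 1, body, author=a, community=community, role=r)
        for i, (body, a, r) in enumerate(zip(bodies, authors, roles))
    )
    return Thread(thread_id=thread_id, posts=posts)


def make_corpus(threads: list[Thread], community: str = "heart",
                moderators: set[str] | None = None) -> Corpus:
    return Corpus(
        community_id=community,
        threads=tuple(threads),
        moderator_ids=frozenset(moderators or set()),
    )


@pytest.fixture
def toy_corpus() -> Corpus:
    """Small hand-built community: 3 threads, one moderator, mixed lengths."""
    t1 = make_thread(
        "t1",
        [
            "bradycardia just means a heart rate below sixty",
            "my heart rate dropped after the beta blocker",
            "ask about a pacemaker if the rate stays low",
        ],
        authors=["ann", "bob", "modx"],
        roles=["user", "user", "md"],
    )
    t2 = make_thread(
        "t2",
        [
            "insurance denied the echo claim again",
            "appeal the claim with a letter from the cardiologist",
        ],
        authors=["cara", "bob"],
    )
    t3 = make_thread("t3", ["lone post that nobody answered"], authors=["dee"])
    return make_corpus([t1, t2, t3], moderators={"modx"})
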