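"""Domain model for threaded forum corpora.

A corpus is one community's threads; each thread is an ordered list of
posts with 1-based positions (position 1 is the original post, the only
post that may carry a title).  Readers validate structure up front so the
downstream similarity analysis can assume contiguous positions and a
well-defined original post per thread.
"""

from __future__ import annotations

import csv
import io
import json
import statistics
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

__all__ = [
    "Post",
    "Thread",
    "Corpus",
    "CorpusStats",
    "CorpusError",
    "ParseError",
    "ValidationError",
    "read_corpus",
    "read_corpora",
    "write_corpus",
    "filter_threads",
    "corpus_stats",
]

ROLE_TAGS = ("user", "staff", "md")
MODERATOR_TAGS = frozenset({"staff", "md"})

CORPUS_FIELDS = (
    "community_id",
    "thread_id",
    "position",
    "author_id",
    "role_tag",
    "title",
    "body",
    "timestamp",
)


class CorpusError(Exception):
    """Base class for corpus reading/validation failures."""


class ParseError(CorpusError):
    """A record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ValidationError(CorpusError):
    """Structurally invalid corpus (duplicate or non-contiguous positions, ...)."""


@dataclass(frozen=True)
class Post:
    """One forum post.

    ``position`` is 1-based; the original post sits at position 1 and is
    the only one allowed a ``title``.  ``role_tag`` records the identity
    the forum displays for the author (plain user, staff moderator, or
    medical doctor).
    """

    community_id: str
    thread_id: str
    position: int
    author_id: str
    role_tag: str
    body: str
    title: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.role_tag not in ROLE_TAGS:
            raise ValidationError(
                f"role_tag must be one of {ROLE_TAGS}, got {self.role_tag!r}"
            )
        if self.title is not None and self.position != 1:
            raise ValidationError(
                f"title present on non-original post "
                f"(thread {self.thread_id}, position {self.position})"
            )

    @property
    def is_original(self) -> bool:
        return self.position == 1


@dataclass(frozen=True)
class Thread:
    """An ordered thread; positions are contiguous 1..L with no duplicates."""

    thread_id: str
    posts: tuple[Post, ...]

    def __post_init__(self) -> None:
        if not self.posts:
            raise ValidationError(f"thread {self.thread_id} has no posts")
        positions = [p.position for p in self.posts]
        if positions != list(range(1, len(self.posts) + 1)):
            raise ValidationError(
                f"thread {self.thread_id}: positions must be contiguous 1..L, "
                f"got {positions}"
            )
        for p in self.posts:
            if p.thread_id != self.thread_id:
                raise ValidationError(
                    f"post thread_id {p.thread_id!r} != thread {self.thread_id!r}"
                )

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def original_post(self) -> Post:
        return self.posts[0]

    @property
    def replies(self) -> tuple[Post, ...]:
        return self.posts[1:]


@dataclass(frozen=True)
class Corpus:
    """All threads of one community plus the set of moderator ids."""

    community_id: str
    threads: tuple[Thread, ...]
    moderator_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for thread in self.threads:
            for post in thread.posts:
                if post.community_id != self.community_id:
                    raise ValidationError(
                        f"post community {post.community_id!r} != corpus "
                        f"community {self.community_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.threads)

    def posts(self) -> Iterator[Post]:
        for thread in self.threads:
            yield from thread.posts

    @property
    def n_posts(self) -> int:
        return sum(len(t) for t in self.threads)


@dataclass(frozen=True)
class CorpusStats:
    """Descriptive statistics of a (filtered) corpus."""

    n_posts: int
    n_threads: int
    n_moderators: int
    n_users: int
    mean_tl: float
    median_tl: float
    max_tl: int


def _post_from_record(rec: dict, line: int) -> Post:
    missing = [k for k in ("community_id", "thread_id", "position", "author_id",
                           "role_tag", "body") if k not in rec or rec[k] is None]
    if missing:
        raise ParseError(f"missing field(s) {missing}", line)
    try:
        position = int(rec["position"])
    except (TypeError, ValueError):
        raise ParseError(f"position is not an integer: {rec['position']!r}", line)
    title = rec.get("title") or None
    timestamp = rec.get("timestamp") or None
    try:
        return Post(
            community_id=str(rec["community_id"]),
            thread_id=str(rec["thread_id"]),
            position=position,
            author_id=str(rec["author_id"]),
            role_tag=str(rec["role_tag"]),
            body=str(rec["body"]),
            title=title,
            timestamp=timestamp,
        )
    except ValidationError as exc:
        raise ParseError(str(exc), line)


def _iter_records(path: Path, format: str) -> Iterator[tuple[dict, int]]:
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for i, raw in enumerate(fh, start=1):
                if not raw.strip():
                    continue
                try:
                    rec = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"invalid JSON ({exc.msg})", i)
                if not isinstance(rec, dict):
                    raise ParseError("record is not a JSON object", i)
                yield rec, i
    elif format == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, rec in enumerate(reader, start=2):  # header is line 1
                yield {k: (v if v != "" else None) for k, v in rec.items()}, i
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson"}:
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(
        f"cannot infer corpus format from {path.name!r}; pass format='jsonl' or 'csv'"
    )


def _build_threads(posts: Sequence[tuple[Post, int]]) -> tuple[Thread, ...]:
    """Group by thread_id and sort by (position, timestamp, input order)."""
    by_thread: dict[str, list[tuple[Post, int]]] = {}
    for post, line in posts:
        by_thread.setdefault(post.thread_id, []).append((post, line))
    threads = []
    for tid, items in by_thread.items():
        seen: dict[int, int] = {}
        for post, line in items:
            if post.position in seen:
                raise ValidationError(
                    f"duplicate (thread_id, position) = ({tid!r}, {post.position}) "
                    f"at lines {seen[post.position]} and {line}"
                )
            seen[post.position] = line
        items.sort(key=lambda it: (it[0].position, it[0].timestamp or "", it[1]))
        threads.append(Thread(thread_id=tid, posts=tuple(p for p, _ in items)))
    threads.sort(key=lambda t: t.thread_id)
    return tuple(threads)


def read_corpora(
    path: str | Path, format: Literal["jsonl", "csv"] | None = None
) -> list[Corpus]:
    """Read a post file, returning one validated :class:`Corpus` per community."""
    path = Path(path)
    format = _infer_format(path, format)
    by_community: dict[str, list[tuple[Post, int]]] = {}
    for rec, line in _iter_records(path, format):
        post = _post_from_record(rec, line)
        by_community.setdefault(post.community_id, []).append((post, line))
    corpora = []
    for cid in sorted(by_community):
        posts = by_community[cid]
        moderators = frozenset(
            p.author_id for p, _ in posts if p.role_tag in MODERATOR_TAGS
        )
        corpora.append(
            Corpus(
                community_id=cid,
                threads=_build_threads(posts),
                moderator_ids=moderators,
            )
        )
    return corpora


def read_corpus(
    path: str | Path,
    format: Literal["jsonl", "csv"] | None = None,
    community_id: str | None = None,
) -> Corpus:
    """Read a single-community corpus.

    If the file contains several communities, ``community_id`` selects one;
    an empty file yields an empty corpus with community_id ``""`` (or the
    requested one).
    """
    corpora = read_corpora(path, format)
    if community_id is not None:
        for corpus in corpora:
            if corpus.community_id == community_id:
                return corpus
        raise ValidationError(f"community {community_id!r} not present in {path}")
    if not corpora:
        return Corpus(community_id=community_id or "", threads=())
    if len(corpora) > 1:
        raise ValidationError(
            f"{path} holds {len(corpora)} communities; pass community_id or use "
            "read_corpora()"
        )
    return corpora[0]


def _post_record(post: Post) -> dict:
    return {
        "community_id": post.community_id,
        "thread_id": post.thread_id,
        "position": post.position,
        "author_id": post.author_id,
        "role_tag": post.role_tag,
        "title": post.title,
        "body": post.body,
        "timestamp": post.timestamp,
    }


def write_corpus(
    corpus: Corpus | Iterable[Corpus],
    path: str | Path,
    format: Literal["jsonl", "csv"] | None = None,
) -> None:
    """Write one or more corpora to JSONL or CSV (round-trips with the readers)."""
    path = Path(path)
    format = _infer_format(path, format)
    corpora = [corpus] if isinstance(corpus, Corpus) else list(corpus)
    records = [_post_record(p) for c in corpora for p in c.posts()]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CORPUS_FIELDS)
            writer.writeheader()
            for rec in records:
                writer.writerow({k: ("" if v is None else v) for k, v in rec.items()})


def filter_threads(corpus: Corpus, min_length: int = 2) -> Corpus:
    """Drop threads without any reply to the original post (length < 2)."""
    kept = tuple(t for t in corpus.threads if len(t) >= min_length)
    return replace(corpus, threads=kept)


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Descriptive statistics over a filtered corpus; errors on an empty one."""
    if not corpus.threads:
        raise ValidationError("corpus_stats undefined for an empty corpus")
    lengths = [len(t) for t in corpus.threads]
    authors = {p.author_id for p in corpus.posts()}
    moderators = set(corpus.moderator_ids) & authors | set(corpus.moderator_ids)
    return CorpusStats(
        n_posts=sum(lengths),
        n_threads=len(lengths),
        n_moderators=len(moderators),
        n_users=len(authors - moderators),
        mean_tl=sum(lengths) / len(lengths),
        median_tl=float(statistics.median(lengths)),
        max_tl=max(lengths),
    )
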