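"""Lexicon flagging of self-identified topic drift.

Community members name drift themselves: "hijack(ed/ing)" for a thread
pulled off its original topic, "off topic"/"off-topic" for content
outside the discussion's focus, and an "OT" title marker for threads
that are deliberately off the community's subject.  Matching is
word-boundary and case-insensitive; body matches and title matches are
reported separately because title conventions carry a different meaning
(announcing an off-topic thread rather than complaining about drift).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Corpus
from .counteraction import TestResult, rank_biserial, _mannwhitney

__all__ = [
    "DEFAULT_LEXICON",
    "OT_TITLE_PATTERN",
    "LexiconFlag",
    "flag_keyword_posts",
    "flag_keyword_titles",
    "flag_ot_titles",
    "compare_offtopic_lengths",
    "flags_to_frame",
]

# Explicit inflection list rather than stemming, so the lexicon is
# reproducible and user-replaceable.
DEFAULT_LEXICON: Mapping[str, str] = {
    "hijack": r"\bhijack(?:ed|ing|er|s)?\b",
    "off_topic": r"\boff[\s-]+topic\b",
}

# Standalone "OT" is a title convention only; in bodies it is too ambiguous.
OT_TITLE_PATTERN = r"\bot\b"


def _compile(lexicon: Mapping[str, str]) -> dict[str, re.Pattern]:
    if not lexicon:
        raise ValueError("lexicon must contain at least one pattern")
    return {name: re.compile(pat, re.IGNORECASE) for name, pat in lexicon.items()}


@dataclass(frozen=True)
class LexiconFlag:
    thread_id: str
    position: int
    matched_terms: tuple[str, ...]
    location: str  # "body" | "title"

    def __post_init__(self) -> None:
        if not self.matched_terms:
            raise ValueError("a LexiconFlag needs at least one matched term")


def _flag(corpus: Corpus, lexicon: Mapping[str, str], location: str) -> list[LexiconFlag]:
    patterns = _compile(lexicon)
    flags = []
    for thread in corpus.threads:
        for post in thread.posts:
            text = post.body if location == "body" else (post.title or "")
            matched = tuple(
                name for name, pat in patterns.items() if pat.search(text)
            )
            if matched:
                flags.append(
                    LexiconFlag(
                        thread_id=thread.thread_id,
                        position=post.position,
                        matched_terms=matched,
                        location=location,
                    )
                )
    return flags


def flag_keyword_posts(
    corpus: Corpus, lexicon: Mapping[str, str] | None = None
) -> list[LexiconFlag]:
    """Posts whose *body* (never the title) matches a lexicon pattern."""
    return _flag(corpus, DEFAULT_LEXICON if lexicon is None else lexicon, "body")


def flag_keyword_titles(
    corpus: Corpus, lexicon: Mapping[str, str] | None = None
) -> list[LexiconFlag]:
    """Title matches, reported separately from body flags."""
    return _flag(corpus, DEFAULT_LEXICON if lexicon is None else lexicon, "title")


def flag_ot_titles(corpus: Corpus) -> list[str]:
    """Threads announcing themselves off topic in the original post's title
    (standalone "OT" token or the "off topic"/"off-topic" phrase)."""
    lexicon = {"ot": OT_TITLE_PATTERN, "off_topic": DEFAULT_LEXICON["off_topic"]}
    flagged = {
        f.thread_id for f in _flag(corpus, lexicon, "title") if f.position == 1
    }
    return sorted(flagged)


def compare_offtopic_lengths(
    corpus: Corpus, flagged: Sequence[str]
) -> TestResult:
    """Mann-Whitney comparison of thread lengths: flagged-as-off-topic
    threads vs all remaining threads, with rank-biserial effect size."""
    flagged_set = set(flagged)
    flagged_lengths = [len(t) for t in corpus.threads if t.thread_id in flagged_set]
    rest_lengths = [len(t) for t in corpus.threads if t.thread_id not in flagged_set]
    if not flagged_lengths or not rest_lengths:
        raise ValueError(
            "both groups must be nonempty "
            f"(flagged={len(flagged_lengths)}, rest={len(rest_lengths)})"
        )
    u, p = _mannwhitney(flagged_lengths, rest_lengths)
    return TestResult(
        test="mann_whitney",
        groups=("off_topic", "rest"),
        statistic=u,
        raw_p=p,
        effect_size=rank_biserial(u, len(flagged_lengths), len(rest_lengths)),
        mean_difference=(
            sum(rest_lengths) / len(rest_lengths)
            - sum(flagged_lengths) / len(flagged_lengths)
        ),
    )


def flags_to_frame(corpus: Corpus, flags: Iterable[LexiconFlag]) -> pd.DataFrame:
    """Flag export with +/-1 post of body context for human review."""
    bodies = {
        (t.thread_id, p.position): p.body for t in corpus.threads for p in t.posts
    }
    rows = []
    for f in flags:
        context = " | ".join(
            bodies[(f.thread_id, pos)]
            for pos in (f.position - 1, f.position, f.position + 1)
            if (f.thread_id, pos) in bodies
        )
        rows.append(
            {
                "thread_id": f.thread_id,
                "position": f.position,
                "matched_terms": ";".join(f.matched_terms),
                "location": f.location,
                "context": context,
            }
        )
    return pd.DataFrame(
        rows, columns=["thread_id", "position", "matched_terms", "location", "context"]
    )
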