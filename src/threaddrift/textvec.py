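"""Tokenization, community-level tf-idf, sparse post vectors and cosine.

Each community gets its own tf-idf model so that term weights reflect
what is distinctive within that community's discussions.  The document
unit is a single post (similarity is computed between posts), tf is the
raw within-post count and idf is ln(N/df) with no smoothing by default;
the vector is not pre-normalized because cosine normalizes.  Titles are
never part of the vectorized text.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import Corpus, Post

__all__ = [
    "tokenize",
    "PostVector",
    "cosine",
    "CommunityTfidf",
    "fit_tfidf",
    "vectorize",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters.

    Hyphens, apostrophes and underscores all split; pure-digit tokens are
    kept.  ``tokenize("off-topic OFF topic")`` -> ``["off", "topic",
    "off", "topic"]``.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class PostVector:
    """Sparse tf-idf vector of one post: term -> nonnegative weight."""

    weights: Mapping[str, float]
    norm: float = field(init=False)

    def __post_init__(self) -> None:
        weights = {t: w for t, w in self.weights.items() if w != 0.0}
        object.__setattr__(self, "weights", weights)
        object.__setattr__(
            self, "norm", math.sqrt(sum(w * w for w in weights.values()))
        )

    @property
    def is_zero(self) -> bool:
        return self.norm == 0.0


def cosine(v1: PostVector, v2: PostVector) -> float:
    """Cosine similarity in [0, 1]; 0 when either vector is all-zero."""
    if v1.norm == 0.0 or v2.norm == 0.0:
        return 0.0
    small, large = (v1, v2) if len(v1.weights) <= len(v2.weights) else (v2, v1)
    dot = sum(w * large.weights.get(t, 0.0) for t, w in small.weights.items())
    return min(1.0, dot / (v1.norm * v2.norm))


class CommunityTfidf(BaseEstimator, TransformerMixin):
    """Community-level tf-idf vectorizer over individual posts.

    Parameters
    ----------
    smooth_idf : bool, default False
        If True use idf = ln((1+N)/(1+df)); default is the plain ln(N/df),
        so a term appearing in every post carries zero weight.
    sublinear_tf : bool, default False
        If True use tf = 1 + ln(count) instead of the raw count.
    stopwords : iterable of str, optional
        Terms dropped at both fit and transform time.  None by default:
        community-level idf already down-weights ubiquitous terms.

    Fitted attributes
    -----------------
    community_id_ : str
    n_docs_ : int              number of posts seen at fit time
    df_ : dict[str, int]       document frequency per term
    vocabulary_ : dict[str, int]
    """

    def __init__(
        self,
        smooth_idf: bool = False,
        sublinear_tf: bool = False,
        stopwords: Iterable[str] | None = None,
    ):
        self.smooth_idf = smooth_idf
        self.sublinear_tf = sublinear_tf
        self.stopwords = stopwords

    # -- fitting -----------------------------------------------------------

    def fit(self, X: Corpus | Sequence[Post], y=None) -> "CommunityTfidf":
        posts = list(X.posts()) if isinstance(X, Corpus) else list(X)
        if not posts:
            raise ValueError("cannot fit tf-idf on zero posts")
        stop = frozenset(self.stopwords or ())
        df: dict[str, int] = {}
        n_nonempty = 0
        for post in posts:
            terms = set(tokenize(post.body)) - stop
            if terms:
                n_nonempty += 1
            for t in terms:
                df[t] = df.get(t, 0) + 1
        if n_nonempty == 0:
            raise ValueError("cannot fit tf-idf: every post tokenizes to nothing")
        communities = {p.community_id for p in posts}
        if len(communities) > 1:
            raise ValueError(
                f"tf-idf is fit per community; got posts from {sorted(communities)}"
            )
        self.community_id_ = posts[0].community_id
        self.n_docs_ = len(posts)
        self.df_ = df
        self.vocabulary_ = {t: i for i, t in enumerate(sorted(df))}
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "df_"):
            raise RuntimeError("CommunityTfidf is not fitted; call fit() first")

    def idf(self, term: str) -> float:
        self._check_fitted()
        df = self.df_.get(term)
        if df is None:
            return 0.0
        if self.smooth_idf:
            return math.log((1 + self.n_docs_) / (1 + df))
        return math.log(self.n_docs_ / df)

    # -- transforming ------------------------------------------------------

    def transform_one(self, post: Post | str) -> PostVector:
        """Vectorize one post (or raw text); unseen terms get weight 0."""
        self._check_fitted()
        text = post.body if isinstance(post, Post) else post
        stop = frozenset(self.stopwords or ())
        counts: dict[str, int] = {}
        for t in tokenize(text):
            if t in stop or t not in self.df_:
                continue
            counts[t] = counts.get(t, 0) + 1
        weights = {}
        for t, c in counts.items():
            tf = 1.0 + math.log(c) if self.sublinear_tf else float(c)
            weights[t] = tf * self.idf(t)
        return PostVector(weights)

    def transform(self, X: Corpus | Iterable[Post | str]) -> list[PostVector]:
        posts = X.posts() if isinstance(X, Corpus) else X
        return [self.transform_one(p) for p in posts]

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted model (config + counts) for reproducible runs."""
        self._check_fitted()
        payload = {
            "community_id": self.community_id_,
            "n_docs": self.n_docs_,
            "df": self.df_,
            "config": {
                "smooth_idf": self.smooth_idf,
                "sublinear_tf": self.sublinear_tf,
                "stopwords": sorted(self.stopwords) if self.stopwords else None,
            },
        }
        text = json.dumps(payload, ensure_ascii=False, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CommunityTfidf":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        payload = json.loads(text)
        model = cls(**payload["config"])
        model.community_id_ = payload["community_id"]
        model.n_docs_ = int(payload["n_docs"])
        model.df_ = {t: int(v) for t, v in payload["df"].items()}
        model.vocabulary_ = {t: i for i, t in enumerate(sorted(model.df_))}
        return model


def fit_tfidf(corpus: Corpus, **params) -> CommunityTfidf:
    """Fit a community-level tf-idf model on all posts of ``corpus``."""
    return CommunityTfidf(**params).fit(corpus)


def vectorize(post: Post | str, model: CommunityTfidf) -> PostVector:
    """Sparse tf-idf vector of one post under a fitted community model."""
    return model.transform_one(post)
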