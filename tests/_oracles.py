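"""Independent brute-force oracles used to cross-check the implementation.

Deliberately dense, index-based and free of any code from the package's
sparse path: documents are token lists, weights live in a full
document-by-term numpy matrix, and cosines come from explicit dot
products (cross-checked against scikit-learn's cosine_similarity).
"""

from __future__ import annotations

import math

import numpy as np


def dense_tfidf(docs: list[list[str]]) -> tuple[np.ndarray, list[str]]:
    """Full tf-idf matrix with tf = raw count and idf = ln(N/df)."""
    vocab = sorted({t for doc in docs for t in doc})
    index = {t: j for j, t in enumerate(vocab)}
    n = len(docs)
    counts = np.zeros((n, len(vocab)))
    for i, doc in enumerate(docs):
        for t in doc:
            counts[i, index[t]] += 1.0
    df = (counts > 0).sum(axis=0)
    idf = np.array([math.log(n / d) if d else 0.0 for d in df])
    return counts * idf, vocab


def dense_cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def brute_force_metrics(predicted: list[bool], gold: list[bool]) -> dict[str, float]:
    """Per-instance counting, no confusion-matrix intermediary."""
    n = len(gold)
    correct = sum(1 for p, g in zip(predicted, gold) if p == g)
    pred_pos = [g for p, g in zip(predicted, gold) if p]
    true_pos_hit = sum(1 for p, g in zip(predicted, gold) if p and g)
    n_gold_pos = sum(gold)
    precision = (true_pos_hit / len(pred_pos)) if pred_pos else 0.0
    recall = (true_pos_hit / n_gold_pos) if n_gold_pos else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "accuracy": correct / n,
        "f1": f1,
    }
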