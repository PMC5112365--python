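"""Confusion matrices and precision/recall/accuracy/F1.

Zero-denominator conventions are explicit because tiny synthetic inputs
hit them: no predicted positives gives precision 0 (with a warning), and
an empty harmonic mean gives F1 0.  Display rounding is half-up to two
decimals; internal values keep full precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "round2"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError(f"confusion-matrix cells must be >= 0, got {cells}")
        if sum(cells) < 1:
            raise ValueError("confusion matrix must count at least one instance")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    accuracy: float
    f1: float

    def rounded(self) -> dict[str, float]:
        """Two-decimal half-up display values (the ".70/.71" style)."""
        return {
            "precision": round2(self.precision),
            "recall": round2(self.recall),
            "accuracy": round2(self.accuracy),
            "f1": round2(self.f1),
        }

    def to_json(self, cm: ConfusionMatrix | None = None) -> str:
        payload: dict = {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "display": {k: f"{v:.2f}" for k, v in self.rounded().items()},
        }
        if cm is not None:
            payload["matrix"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        return json.dumps(payload, sort_keys=True)


def round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion(predicted: Sequence[bool], gold: Sequence[bool]) -> ConfusionMatrix:
    """Count the four cells; the positive class is the caller's (drift or
    counteraction)."""
    if len(predicted) != len(gold):
        raise ValueError(
            f"predicted and gold must have equal length "
            f"({len(predicted)} != {len(gold)})"
        )
    if len(predicted) == 0:
        raise ValueError("need at least one instance")
    tp = fp = fn = tn = 0
    for p, g in zip(predicted, gold):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is 0; reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    accuracy = (cm.tp + cm.tn) / cm.total
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(precision=precision, recall=recall, accuracy=accuracy, f1=f1)
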