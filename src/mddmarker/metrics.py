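"""Confusion matrices and classification performance statistics.

Responders (RES) are the positive class throughout: sensitivity is the
fraction of true responders identified, specificity the fraction of true
non-responders identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

RES = "RES"
NRES = "NRES"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 tally with RES as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, sensitivity, specificity, precision and F1, each in [0, 1].

    Ratios with a zero denominator are reported as 0.0 and listed in
    ``undefined`` rather than returned as NaN, so selection criteria that
    compare metrics stay total.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = field(default=())

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Half-up rounding for report display (e.g. 0.875 -> 0.88)."""
        return {
            k: round_half_up(getattr(self, k), ndigits)
            for k in ("accuracy", "sensitivity", "specificity", "precision", "f1")
        }


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(
    predicted: Mapping[str, str] | Sequence[str],
    truth: Mapping[str, str] | Sequence[str],
) -> ConfusionMatrix:
    """Tally a confusion matrix from predicted and true RES/NRES labels.

    Accepts either two parallel sequences or two mappings keyed by sample id;
    mappings must cover identical sample ids.
    """
    if isinstance(predicted, Mapping) != isinstance(truth, Mapping):
        raise TypeError("predicted and truth must both be mappings or both sequences")
    if isinstance(predicted, Mapping):
        if set(predicted) != set(truth):
            missing = set(predicted) ^ set(truth)
            raise ValueError(f"sample ids differ between predictions and truth: {sorted(missing)}")
        ids = sorted(predicted)
        pred = [predicted[i] for i in ids]
        true = [truth[i] for i in ids]
    else:
        if len(predicted) != len(truth):
            raise ValueError("predicted and truth have different lengths")
        pred, true = list(predicted), list(truth)
    for lab in (*pred, *true):
        if lab not in (RES, NRES):
            raise ValueError(f"unknown label {lab!r}; expected RES or NRES")
    tp = sum(p == RES and t == RES for p, t in zip(pred, true))
    fn = sum(p == NRES and t == RES for p, t in zip(pred, true))
    fp = sum(p == RES and t == NRES for p, t in zip(pred, true))
    tn = sum(p == NRES and t == NRES for p, t in zip(pred, true))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def compute_metrics(m: ConfusionMatrix) -> ClassificationMetrics:
    """The five reported statistics from a confusion matrix.

    accuracy = (tp+tn)/total, sensitivity = tp/(tp+fn),
    specificity = tn/(tn+fp), precision = tp/(tp+fp),
    f1 = harmonic mean of precision and sensitivity.
    """
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (m.tp + m.tn) / m.total
    sensitivity = ratio(m.tp, m.tp + m.fn, "sensitivity")
    specificity = ratio(m.tn, m.tn + m.fp, "specificity")
    precision = ratio(m.tp, m.tp + m.fp, "precision")
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        undefined.append("f1")
        f1 = 0.0
    return ClassificationMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        undefined=tuple(undefined),
    )
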