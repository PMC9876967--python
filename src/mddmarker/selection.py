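"""Leave-one-out marker-combination selection with frequency voting.

Each training sample is held out once; on the remaining sub-training samples
every k-marker combination is scored by *re-substitution* — the discrete Bayes
classifier is discretized and fitted on the sub-training samples restricted to
the combination's markers, then those same samples are reclassified — and one
combination is chosen per fold by the configured criterion (maximal
sensitivity subject to a specificity floor, or maximal F1). The combination
chosen most often across folds wins. The held-out sample is never touched,
and discretization is re-fit inside every fold, so no information leaks out
of the sub-training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import bayes
from .metrics import NRES, RES, ClassificationMetrics, ConfusionMatrix, compute_metrics


@dataclass(frozen=True)
class ClassifierConfig:
    """Discretization and smoothing settings shared across folds."""

    divisions: int = 2
    epsilon: float = 0.5
    conditional: bayes.Conditional = "cross_marker"


@dataclass(frozen=True)
class SelectionCriterion:
    """Per-fold combination choice rule.

    ``sensitivity_with_specificity_floor``: among combinations with
    specificity >= ``specificity_floor``, pick maximal sensitivity (fall back
    to maximal specificity, flagged, if none reaches the floor).
    ``f1``: pick maximal F1. Ties break by higher accuracy, then
    lexicographically by the (sorted) marker tuple.
    """

    mode: Literal["sensitivity_with_specificity_floor", "f1"] = (
        "sensitivity_with_specificity_floor"
    )
    specificity_floor: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.specificity_floor <= 1:
            raise ValueError("specificity_floor must lie in [0, 1]")


@dataclass(frozen=True)
class FoldSelection:
    left_out: str
    combination: tuple[str, ...]
    metrics: ClassificationMetrics
    floor_fallback: bool = False


@dataclass
class SelectionResult:
    """Outcome of the leave-one-out vote."""

    winner: tuple[str, ...]
    frequencies: dict[tuple[str, ...], int]
    folds: list[FoldSelection]
    criterion: SelectionCriterion
    k: int
    evaluations: int = 0
    tie_break_used: bool = False
    mean_f1: dict[tuple[str, ...], float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "winner": list(self.winner),
            "k": self.k,
            "criterion": {
                "mode": self.criterion.mode,
                "specificity_floor": self.criterion.specificity_floor,
            },
            "frequencies": {",".join(c): n for c, n in sorted(self.frequencies.items())},
            "tie_break_used": self.tie_break_used,
            "evaluations": self.evaluations,
            "folds": [
                {
                    "left_out": f.left_out,
                    "combination": list(f.combination),
                    "floor_fallback": f.floor_fallback,
                    "sensitivity": f.metrics.sensitivity,
                    "specificity": f.metrics.specificity,
                    "f1": f.metrics.f1,
                }
                for f in self.folds
            ],
        }


def enumerate_combinations(markers: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All C(n, k) k-marker combinations in lexicographic order."""
    markers = sorted(markers)
    if k > len(markers):
        raise ValueError(f"k={k} exceeds the number of markers ({len(markers)})")
    if len(set(markers)) != len(markers):
        raise ValueError("marker ids must be distinct")
    return list(itertools.combinations(markers, k))


def resubstitution_metrics(
    values: pd.DataFrame,
    labels: pd.Series,
    combination: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationMetrics:
    """Fit on the given samples restricted to the combination, reclassify them.

    ``values`` holds raw (continuous) marker values, samples x markers.
    """
    sub = values[list(combination)]
    scheme = bayes.fit_discretization(sub, config.divisions)
    disc = bayes.discretize_frame(scheme, sub)
    model = bayes.fit_model(disc, labels, scheme, config.epsilon, config.conditional)
    pred = bayes.classify_frame(model, disc)
    return _metrics_from_predictions(pred["label"], labels.reindex(values.index))


def _metrics_from_predictions(pred: pd.Series, truth: pd.Series) -> ClassificationMetrics:
    t = truth.to_numpy()
    p = pred.to_numpy()
    cm = ConfusionMatrix(
        tp=int(((p == RES) & (t == RES)).sum()),
        fn=int(((p == NRES) & (t == RES)).sum()),
        fp=int(((p == RES) & (t == NRES)).sum()),
        tn=int(((p == NRES) & (t == NRES)).sum()),
    )
    return compute_metrics(cm)


def select_per_fold(
    evaluated: Sequence[tuple[tuple[str, ...], ClassificationMetrics]],
    criterion: SelectionCriterion,
) -> tuple[tuple[str, ...], ClassificationMetrics, bool]:
    """Apply the criterion to pre-computed (combination, metrics) pairs.

    Returns (combination, metrics, floor_fallback_flag).
    """
    if not evaluated:
        raise ValueError("no candidate combinations to select from")
    # lexicographic tie-break comes last: sort candidates by combination first
    cands = sorted(evaluated, key=lambda cm: cm[0])
    if criterion.mode == "f1":
        best = max(cands, key=lambda cm: (cm[1].f1, cm[1].accuracy, _neg_lex(cm[0])))
        return best[0], best[1], False
    if criterion.mode == "sensitivity_with_specificity_floor":
        meeting = [cm for cm in cands if cm[1].specificity >= criterion.specificity_floor]
        if meeting:
            best = max(
                meeting, key=lambda cm: (cm[1].sensitivity, cm[1].accuracy, _neg_lex(cm[0]))
            )
            return best[0], best[1], False
        best = max(cands, key=lambda cm: (cm[1].specificity, cm[1].accuracy, _neg_lex(cm[0])))
        return best[0], best[1], True
    raise ValueError(f"unknown criterion mode {criterion.mode!r}")


class _neg_lex:
    """Ordering helper: prefers lexicographically smaller tuples under max()."""

    __slots__ = ("t",)

    def __init__(self, t: tuple[str, ...]):
        self.t = t

    def __lt__(self, other: "_neg_lex") -> bool:
        return self.t > other.t

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_lex) and self.t == other.t


def _fold_counts(
    disc: np.ndarray, labels_res: np.ndarray, n_div: np.ndarray
) -> np.ndarray:
    """Per-class, per-marker, per-division counts from 0-based division indices."""
    n, m = disc.shape
    max_d = int(n_div.max())
    counts = np.zeros((2, m, max_d), dtype=int)
    for j in range(m):
        counts[0, j] = np.bincount(disc[labels_res, j], minlength=max_d)
        counts[1, j] = np.bincount(disc[~labels_res, j], minlength=max_d)
    return counts


def _combo_metrics(
    counts: np.ndarray,
    disc: np.ndarray,
    labels_res: np.ndarray,
    combo_idx: tuple[int, ...],
    config: ClassifierConfig,
    n_div: np.ndarray,
) -> ClassificationMetrics:
    """Re-substitution metrics of one combination, vectorized over samples."""
    eps = config.epsilon
    j = np.array(combo_idx)
    obs = counts[:, j[None, :], disc[:, j]].astype(float)  # (2, n, |k|)
    if config.conditional == "cross_marker":
        denom = obs.sum(axis=2, keepdims=True) + eps * len(j)
    else:
        totals = counts[:, j].sum(axis=2).astype(float) + eps * n_div[j]
        denom = totals[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = (obs + eps) / denom
    cond = np.nan_to_num(cond, nan=0.0)
    lik = cond.prod(axis=2)  # (2, n)
    if np.any(lik.sum(axis=0) == 0):
        raise ValueError(
            "zero class-conditional probability under both classes; use epsilon > 0"
        )
    pred_res = lik[0] >= lik[1]  # ties -> RES
    tp = int((pred_res & labels_res).sum())
    fn = int((~pred_res & labels_res).sum())
    fp = int((pred_res & ~labels_res).sum())
    tn = int((~pred_res & ~labels_res).sum())
    return compute_metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))


def loo_select(
    values: pd.DataFrame,
    labels: pd.Series,
    markers: Sequence[str] | None = None,
    k: int = 2,
    criterion: SelectionCriterion = SelectionCriterion(),
    config: ClassifierConfig = ClassifierConfig(),
) -> SelectionResult:
    """Leave-one-out frequency voting over all C(n, k) marker combinations.

    ``values``: training samples x markers (raw continuous values).
    Each sample is left out once; on the remaining samples the discretization
    is re-fit per marker, every combination's re-substitution metrics are
    computed, and the criterion picks one combination. The most frequent
    choice across folds is the winner; frequency ties break by higher mean
    re-substitution F1 across folds, then lexicographically.
    """
    labels = labels.reindex(values.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    if markers is None:
        markers = list(values.columns)
    markers = sorted(markers)
    combos = enumerate_combinations(markers, k)
    combo_idx = [tuple(markers.index(m) for m in c) for c in combos]
    n_res = int((labels == RES).sum())
    n_nres = int((labels == NRES).sum())
    if n_res < 3 or n_nres < 3:
        raise ValueError("need at least 3 training samples per class")

    x = values[markers].to_numpy(dtype=float)
    is_res = (labels == RES).to_numpy()
    n = len(values)

    folds: list[FoldSelection] = []
    freq: dict[tuple[str, ...], int] = {}
    f1_sums: dict[tuple[str, ...], float] = {c: 0.0 for c in combos}
    evaluations = 0

    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = x[keep]
        sub_res = is_res[keep]
        sub_frame = pd.DataFrame(sub, columns=markers)
        scheme = bayes.fit_discretization(sub_frame, config.divisions)
        disc = bayes.discretize_frame(scheme, sub_frame).to_numpy(dtype=int) - 1
        n_div = np.array([scheme.n_divisions(m) for m in markers])
        counts = _fold_counts(disc, sub_res, n_div)
        evaluated = []
        for c, ci in zip(combos, combo_idx):
            met = _combo_metrics(counts, disc, sub_res, ci, config, n_div)
            f1_sums[c] += met.f1
            evaluated.append((c, met))
        evaluations += len(evaluated)
        chosen, met, fallback = select_per_fold(evaluated, criterion)
        folds.append(
            FoldSelection(
                left_out=str(values.index[i]),
                combination=chosen,
                metrics=met,
                floor_fallback=fallback,
            )
        )
        freq[chosen] = freq.get(chosen, 0) + 1

    mean_f1 = {c: f1_sums[c] / n for c in combos}
    max_freq = max(freq.values())
    top = sorted(c for c, v in freq.items() if v == max_freq)
    tie_break = len(top) > 1
    winner = max(top, key=lambda c: (mean_f1[c], _neg_lex(c)))
    return SelectionResult(
        winner=winner,
        frequencies=freq,
        folds=folds,
        criterion=criterion,
        k=k,
        evaluations=evaluations,
        tie_break_used=tie_break,
        mean_f1=mean_f1,
    )
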