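"""Discrete Bayes decision rule over discretized biomarkers.

Continuous marker values (e.g. qPCR fold changes) are discretized into a small
number of divisions per marker; per-class division counts from the training set
yield class-conditional probabilities, and a sample is assigned the class with
maximum posterior. Priors are fixed equal for the two classes (RES, NRES).

Two conditional-probability normalizations are supported:

``cross_marker`` (default)
    P(x_j(d)|w_i) = (n_j(d)i + eps) / sum_k (n_k(d_k)i + eps), where the
    denominator sums, over every marker k in the model, the class-i training
    count of the division that *this sample* occupies in marker k. With a
    single marker the two normalizations coincide.

``per_marker``
    Standard categorical naive Bayes: the denominator is the class-i total
    over the divisions of marker j itself, sum_d (n_j(d)i + eps).

The additive smoothing constant eps (default 0.5) guards against divisions
never seen in one class; eps = 0 gives the unsmoothed rule, which raises an
error when a sample's division pattern has zero probability under both classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import NRES, RES

Conditional = Literal["cross_marker", "per_marker"]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Interior cut points per marker; D_j = len(cuts)+1 divisions."""

    cuts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for marker, c in self.cuts.items():
            c = np.asarray(c, dtype=float)
            if c.size < 1:
                raise ValueError(f"marker {marker!r}: at least one cut point required")
            if not np.all(np.diff(c) > 0):
                raise ValueError(f"marker {marker!r}: cut points must be strictly increasing")
            self.cuts[marker] = c

    @property
    def markers(self) -> list[str]:
        return list(self.cuts)

    def n_divisions(self, marker: str) -> int:
        return len(self.cuts[marker]) + 1


@dataclass(frozen=True)
class Posterior:
    p_res: float
    p_nres: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_res <= 1 and 0 <= self.p_nres <= 1):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if abs(self.p_res + self.p_nres - 1.0) > 1e-12:
            raise ValueError("posterior probabilities must sum to 1")


@dataclass
class DiscreteBayesModel:
    """Fitted discretization scheme plus per-class division counts.

    ``counts[i, j, d]`` is the number of class-i training samples whose marker
    j fell in division d (classes ordered [RES, NRES], divisions 0-based
    internally, 1-based in the public discretize/posterior API).
    """

    scheme: DiscretizationScheme
    counts: np.ndarray
    classes: tuple[str, str] = (RES, NRES)
    epsilon: float = 0.5
    conditional: Conditional = "cross_marker"
    priors: tuple[float, float] = (0.5, 0.5)
    n_train: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "classes": list(self.classes),
            "epsilon": self.epsilon,
            "conditional": self.conditional,
            "priors": list(self.priors),
            "markers": self.scheme.markers,
            "cuts": {m: self.scheme.cuts[m].tolist() for m in self.scheme.markers},
            "counts": self.counts.tolist(),
            "n_train": self.n_train,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesModel":
        d = json.loads(text)
        scheme = DiscretizationScheme({m: np.asarray(c, dtype=float) for m, c in d["cuts"].items()})
        return cls(
            scheme=scheme,
            counts=np.asarray(d["counts"], dtype=int),
            classes=tuple(d["classes"]),
            epsilon=d["epsilon"],
            conditional=d["conditional"],
            priors=tuple(d["priors"]),
            n_train={k: int(v) for k, v in d["n_train"].items()},
        )


def fit_discretization(
    values: pd.DataFrame,
    divisions: int | Mapping[str, int] = 2,
) -> DiscretizationScheme:
    """Equal-frequency (quantile) cut points from pooled training values.

    Parameters
    ----------
    values
        samples x markers table of raw (continuous) marker values.
    divisions
        Number of divisions per marker, either one integer for all markers or
        a mapping marker -> D_j. Each D_j must be >= 2 and the marker must have
        at least D_j distinct training values.
    """
    cuts: dict[str, np.ndarray] = {}
    for marker in values.columns:
        d = divisions if isinstance(divisions, int) else divisions[marker]
        if d < 2:
            raise ValueError(f"marker {marker!r}: need at least 2 divisions, got {d}")
        v = np.asarray(values[marker], dtype=float)
        if np.unique(v).size < d:
            raise ValueError(
                f"marker {marker!r}: needs >= {d} distinct training values "
                f"for {d} divisions, found {np.unique(v).size}"
            )
        q = np.quantile(v, np.arange(1, d) / d)
        if not np.all(np.diff(q) > 0):
            raise ValueError(f"marker {marker!r}: ties make quantile cuts non-distinct")
        cuts[marker] = q
    return DiscretizationScheme(cuts)


def discretize(scheme: DiscretizationScheme, values: Mapping[str, float] | pd.Series) -> dict[str, int]:
    """Map raw marker values to 1-based division indices.

    A value exactly equal to a cut point is assigned to the lower division
    (left-closed convention); values beyond the outermost cuts fall in the
    end divisions, which are unbounded.
    """
    out: dict[str, int] = {}
    for marker in scheme.markers:
        if marker not in values or values[marker] is None or (
            isinstance(values[marker], float) and np.isnan(values[marker])
        ):
            raise ValueError(f"missing value for marker {marker!r}")
        out[marker] = int(np.searchsorted(scheme.cuts[marker], values[marker], side="left")) + 1
    return out


def discretize_frame(scheme: DiscretizationScheme, values: pd.DataFrame) -> pd.DataFrame:
    """Vectorized discretize over a samples x markers table."""
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing marker values in columns {bad}")
    cols = {
        m: np.searchsorted(scheme.cuts[m], values[m].to_numpy(dtype=float), side="left") + 1
        for m in scheme.markers
    }
    return pd.DataFrame(cols, index=values.index)


def fit_model(
    discretized: pd.DataFrame,
    labels: pd.Series,
    scheme: DiscretizationScheme,
    epsilon: float = 0.5,
    conditional: Conditional = "cross_marker",
) -> DiscreteBayesModel:
    """Tally per-class, per-marker, per-division training counts.

    ``discretized`` holds 1-based division indices (one column per marker in
    the scheme); ``labels`` gives RES/NRES per sample. Both classes must be
    present.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    labels = labels.reindex(discretized.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    present = set(labels)
    if present != {RES, NRES}:
        raise ValueError(f"both classes RES and NRES must be present, got {sorted(present)}")
    markers = scheme.markers
    max_d = max(scheme.n_divisions(m) for m in markers)
    counts = np.zeros((2, len(markers), max_d), dtype=int)
    for i, cls in enumerate((RES, NRES)):
        sub = discretized.loc[labels == cls, markers]
        for j, m in enumerate(markers):
            dj = scheme.n_divisions(m)
            idx = sub[m].to_numpy(dtype=int)
            if idx.min() < 1 or idx.max() > dj:
                raise ValueError(f"division index out of range for marker {m!r}")
            counts[i, j, :dj] = np.bincount(idx - 1, minlength=dj)
    n_train = {RES: int((labels == RES).sum()), NRES: int((labels == NRES).sum())}
    return DiscreteBayesModel(
        scheme=scheme,
        counts=counts,
        epsilon=epsilon,
        conditional=conditional,
        n_train=n_train,
    )


def _likelihoods(model: DiscreteBayesModel, div_idx: np.ndarray) -> np.ndarray:
    """Class-conditional likelihoods for samples given as (n, m) 0-based divisions."""
    eps = model.epsilon
    m = len(model.scheme.markers)
    # counts at each sample's observed division: shape (2, n, m)
    obs = model.counts[:, np.arange(m), div_idx].astype(float)
    if model.conditional == "cross_marker":
        denom = obs.sum(axis=2, keepdims=True) + eps * m
    elif model.conditional == "per_marker":
        totals = model.counts.sum(axis=2).astype(float)  # (2, m)
        n_div = np.array([model.scheme.n_divisions(k) for k in model.scheme.markers])
        denom = (totals + eps * n_div)[:, None, :]
    else:
        raise ValueError(f"unknown conditional {model.conditional!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = (obs + eps) / denom
    cond = np.nan_to_num(cond, nan=0.0)
    return cond.prod(axis=2)  # (2, n)


def posterior(model: DiscreteBayesModel, sample: Mapping[str, int]) -> Posterior:
    """Posterior class probabilities for one discretized sample.

    Equal priors cancel, so the posterior is the normalized product of the
    per-marker class-conditional probabilities.
    """
    markers = model.scheme.markers
    div = np.array([[sample[m] - 1 for m in markers]], dtype=int)
    for j, m in enumerate(markers):
        if not 0 <= div[0, j] < model.scheme.n_divisions(m):
            raise ValueError(f"division index {sample[m]} out of range for marker {m!r}")
    lik = _likelihoods(model, div)[:, 0]
    total = lik.sum()
    if total == 0:
        raise ValueError(
            "zero class-conditional probability under both classes; "
            "use smoothing epsilon > 0"
        )
    return Posterior(p_res=float(lik[0] / total), p_nres=float(lik[1] / total))


def classify(model: DiscreteBayesModel, sample: Mapping[str, int]) -> tuple[str, bool]:
    """Assign the maximum-posterior class; exact ties go to RES with a flag."""
    p = posterior(model, sample)
    if p.p_res == p.p_nres:
        return RES, True
    return (RES, False) if p.p_res > p.p_nres else (NRES, False)


def classify_frame(model: DiscreteBayesModel, discretized: pd.DataFrame) -> pd.DataFrame:
    """Batch classification; returns p_res, p_nres, label and tie_flag per sample."""
    markers = model.scheme.markers
    div = discretized[markers].to_numpy(dtype=int) - 1
    lik = _likelihoods(model, div)
    total = lik.sum(axis=0)
    if np.any(total == 0):
        bad = discretized.index[total == 0].tolist()
        raise ValueError(
            f"zero class-conditional probability under both classes for samples {bad}; "
            "use smoothing epsilon > 0"
        )
    p_res = lik[0] / total
    p_nres = lik[1] / total
    tie = p_res == p_nres
    label = np.where(p_res >= p_nres, RES, NRES)
    return pd.DataFrame(
        {"p_res": p_res, "p_nres": p_nres, "label": label, "tie_flag": tie},
        index=discretized.index,
    )
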