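"""qPCR absolute quantification and group comparison.

A per-gene standard curve (ordinary least squares of Cq on log10 concentration
over a dilution series) converts Cq values to template concentrations in fM.
Duplicate reactions are quantified individually and averaged on the
concentration scale (configurable to Cq-mean). Expression is normalized as the
ratio of each gene to the B2M reference, anchored so the responder-group mean
ratio equals 1, and groups are compared with two-sided pooled-variance
(Student's) t-tests under Holm step-down correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import NRES, RES

DEFAULT_CONCENTRATIONS_FM = (10.0, 5.0, 2.5, 1.25, 0.625, 0.3125)


@dataclass(frozen=True)
class DilutionSeries:
    """Known-concentration calibration points (concentration in fM, Cq in cycles)."""

    gene: str
    concentrations_fM: np.ndarray
    cq: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_fM, dtype=float)
        q = np.asarray(self.cq, dtype=float)
        if c.size != q.size:
            raise ValueError("concentrations and cq must have equal length")
        if c.size < 3:
            raise ValueError(f"gene {self.gene!r}: need at least 3 dilution points, got {c.size}")
        if (c <= 0).any():
            raise ValueError(f"gene {self.gene!r}: concentrations must be strictly positive")
        if np.unique(c).size != c.size:
            raise ValueError(f"gene {self.gene!r}: duplicate concentrations in dilution series")
        object.__setattr__(self, "concentrations_fM", c)
        object.__setattr__(self, "cq", q)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line Cq = intercept + slope * log10(concentration_fM).

    The intercept is the Cq at 1 fM. A slope near -3.32 corresponds to perfect
    doubling per cycle; a non-negative slope marks a failed amplification and
    sets ``invalid_slope``.
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float
    invalid_slope: bool = False


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """Ordinary least squares of Cq on log10(concentration)."""
    x = np.log10(series.concentrations_fM)
    fit = stats.linregress(x, series.cq)
    r2 = float(fit.rvalue**2)
    invalid = fit.slope >= 0
    if invalid:
        warnings.warn(
            f"gene {series.gene!r}: non-negative standard-curve slope "
            f"({fit.slope:.3f}); amplification looks invalid",
            stacklevel=2,
        )
    return StandardCurve(
        gene=series.gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        invalid_slope=bool(invalid),
    )


def quantify(curve: StandardCurve, cq: float | np.ndarray) -> float | np.ndarray:
    """Invert the standard curve: concentration = 10**((cq - intercept) / slope)."""
    if curve.slope >= 0:
        raise ValueError(
            f"gene {curve.gene!r}: cannot quantify with non-negative slope {curve.slope:.3f}"
        )
    conc = 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)
    return float(conc) if np.isscalar(cq) or np.ndim(cq) == 0 else conc


def quantify_plate(
    plate: pd.DataFrame,
    curves: dict[str, StandardCurve],
    combine: Literal["concentration", "cq"] = "concentration",
) -> pd.DataFrame:
    """Per sample x gene concentration from duplicate Cq measurements.

    ``plate`` is a long table (sample_id, gene, replicate, cq). With
    ``combine="concentration"`` each replicate is quantified individually and
    the concentrations are averaged; with ``combine="cq"`` replicates' Cq
    values are averaged before a single inversion.
    """
    required = {"sample_id", "gene", "replicate", "cq"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    rows: dict[str, dict[str, float]] = {}
    for (sample, gene), grp in plate.groupby(["sample_id", "gene"], sort=False):
        if gene not in curves:
            raise ValueError(f"no standard curve for gene {gene!r}")
        curve = curves[gene]
        if combine == "concentration":
            value = float(np.mean(quantify(curve, grp["cq"].to_numpy())))
        elif combine == "cq":
            value = float(quantify(curve, float(grp["cq"].mean())))
        else:
            raise ValueError(f"unknown combine mode {combine!r}")
        rows.setdefault(sample, {})[gene] = value
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def fold_changes(
    gene_quantities: pd.DataFrame,
    b2m_quantities: pd.Series,
    labels: pd.Series,
) -> pd.DataFrame:
    """B2M-normalized fold changes anchored at the responder mean.

    Per sample the ratio gene/B2M is formed, then each gene's column is
    divided by its mean over RES samples, so the responder mean is exactly 1.
    """
    b2m = b2m_quantities.reindex(gene_quantities.index)
    bad = b2m.index[(b2m.isna()) | (b2m <= 0)].tolist()
    if bad:
        raise ValueError(f"non-positive or missing B2M quantity for samples: {bad}")
    labels = labels.reindex(gene_quantities.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    if not (labels == RES).any():
        raise ValueError("no RES samples to anchor fold changes")
    ratio = gene_quantities.div(b2m, axis=0)
    res_mean = ratio.loc[labels == RES].mean(axis=0)
    if (res_mean <= 0).any():
        bad_genes = res_mean.index[res_mean <= 0].tolist()
        raise ValueError(f"non-positive responder mean ratio for genes: {bad_genes}")
    return ratio.div(res_mean, axis=1)


def compare_groups(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sided pooled-variance t-test per gene with Holm correction.

    Returns a DataFrame (gene, t, p, p_holm, zero_variance) ordered as the
    input columns. Genes whose pooled variance is zero get t = 0, p = 1 and a
    warning flag.
    """
    labels = labels.reindex(table.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    res = table.loc[labels == RES]
    nres = table.loc[labels == NRES]
    if len(res) < 2 or len(nres) < 2:
        raise ValueError("each group needs at least 2 samples")
    t_stats, pvals, flags = [], [], []
    for gene in table.columns:
        a = res[gene].to_numpy(dtype=float)
        b = nres[gene].to_numpy(dtype=float)
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            warnings.warn(f"gene {gene!r}: zero pooled variance; p set to 1", stacklevel=2)
            t_stats.append(0.0)
            pvals.append(1.0)
            flags.append(True)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t_stats.append(float(t))
        pvals.append(float(p))
        flags.append(False)
    _, p_holm, _, _ = multipletests(pvals, method="holm")
    return pd.DataFrame(
        {
            "gene": table.columns,
            "t": t_stats,
            "p": pvals,
            "p_holm": p_holm,
            "zero_variance": flags,
        }
    ).reset_index(drop=True)
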