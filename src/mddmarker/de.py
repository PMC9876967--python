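"""Differential-expression screening of a two-group count matrix.

Normalization follows the trimmed mean of M-values (TMM) method: per-gene
log2 ratios against a reference sample are doubly trimmed (30% on M, 5% on
average abundance A) and combined by an inverse-variance weighted mean; the
reference is the sample whose upper-quartile expression is closest to the mean
upper quartile. The returned :class:`NormalizationFactors` are *effective*
per-sample scales — library size times the TMM component — rescaled to
geometric mean 1, so that downstream model offsets are simply log(factor).

Testing is a per-gene likelihood-ratio test between a two-group-mean and a
single-mean negative-binomial model with per-sample offsets; the statistic is
referred to chi-square with 1 degree of freedom. Dispersion is estimated by a
pooled within-group method of moments on normalized counts, floored at 1e-8
and by default averaged into a single common value across genes (per-gene
estimates are available via ``dispersion="tagwise"``). Candidate filtering applies the screening thresholds P < 0.01 and
two-sided linear fold change > 1.5; validation targets are the top genes by
p-value among candidates with raw mean count >= 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .metrics import NRES, RES

_TRIM_M = 0.30
_TRIM_A = 0.05
_DISP_FLOOR = 1e-8
_PSEUDO = 0.5


@dataclass(frozen=True)
class NormalizationFactors:
    """Effective per-sample scale factors with geometric mean 1."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        f = self.factors
        if (f <= 0).any():
            raise ValueError("normalization factors must be positive")
        if abs(np.exp(np.log(f.to_numpy()).mean()) - 1.0) > 1e-9:
            raise ValueError("normalization factors must have geometric mean 1")


@dataclass(frozen=True)
class DEGeneResult:
    gene: str
    log2fc: float
    pvalue: float
    mean_count: float
    passes_filter: bool


def _upper_quartile(matrix: np.ndarray, libsize: np.ndarray) -> np.ndarray:
    return np.quantile(matrix, 0.75, axis=0) / libsize


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, weighted: bool = False
) -> float:
    """TMM scaling component of one sample against the reference.

    Mirrors the doubly-trimmed mean of per-gene log2 ratios: genes outside the
    central 40% of M-values or the central 90% of average abundances are
    discarded. ``weighted=True`` applies inverse asymptotic-variance weights
    (the delta-method binomial variances); the unweighted default keeps the
    factors exactly equivariant under rescaling a whole sample.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * _TRIM_M) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * _TRIM_A) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    return float(2.0**f)


def compute_tmm_factors(matrix: pd.DataFrame, weighted: bool = False) -> NormalizationFactors:
    """Effective per-sample scale factors by trimmed mean of M-values.

    The returned factors are library size times the TMM component, rescaled
    to geometric mean 1; multiplying one sample's counts by a constant scales
    its factor (relative to the others) by exactly that constant. Genes with
    a zero count in either the sample or the reference drop out of the
    trimmed set (their M-values are not finite). Raises if any sample has
    zero total count.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = x.sum(axis=0)
    if (libsize == 0).any():
        dead = matrix.columns[libsize == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {dead}")
    uq = _upper_quartile(x, libsize)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    tmm = np.array(
        [
            _tmm_pair(x[:, k], x[:, ref_idx], libsize[k], libsize[ref_idx], weighted)
            for k in range(x.shape[1])
        ]
    )
    eff = libsize * tmm
    eff = eff / np.exp(np.mean(np.log(eff)))
    return NormalizationFactors(
        factors=pd.Series(eff, index=matrix.columns, name="factor"),
        reference_sample=str(matrix.columns[ref_idx]),
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood, summed over samples. mu may contain 0 where y = 0."""
    r = 1.0 / alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    ll = np.where((y == 0) & (mu == 0), 0.0, ll)
    return np.nansum(ll, axis=1)


def _fit_nb_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene MLE of the mean rate q in mu_j = s_j * q with fixed dispersion.

    Newton iterations on beta = log q; the NB2 log-likelihood is concave in
    beta, so a handful of damped steps converges.
    """
    tot = y.sum(axis=1)
    q = np.where(tot > 0, tot / s.sum(), np.nan)
    beta = np.log(q)
    for _ in range(60):
        mu = s[None, :] * np.exp(beta)[:, None]
        w = 1.0 + alpha[:, None] * mu
        score = np.nansum((y - mu) / w, axis=1)
        info = np.nansum(mu * (1.0 + alpha[:, None] * y) / w**2, axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.nanmax(np.abs(step), initial=0.0) < 1e-12:
            break
    q = np.exp(beta)
    return np.where(tot > 0, q, 0.0)


def _mom_dispersion(
    z: np.ndarray,
    groups: list[np.ndarray],
    inv_s_mean: float,
    mode: str = "common",
) -> np.ndarray:
    """Method-of-moments NB dispersion from normalized counts.

    Pooled within-group variances give per-gene moment estimates
    alpha = (var - mean * mean(1/s)) / mean^2 (the mean(1/s) term accounts
    for the library-scale division). ``mode="common"`` averages the per-gene
    estimates into one shared dispersion — plugging noisy per-gene moment
    estimates into the chi-square reference makes the LRT anticonservative at
    cohort sizes of a few dozen samples, while a common dispersion keeps it
    calibrated; ``mode="tagwise"`` keeps the per-gene estimates.
    """
    n_genes = z.shape[0]
    num = np.zeros(n_genes)
    den = 0.0
    mean_all = np.zeros(n_genes)
    w_all = 0.0
    for idx in groups:
        zg = z[:, idx]
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        df = len(idx) - 1
        num += v * df
        den += df
        mean_all += m * len(idx)
        w_all += len(idx)
    v_pooled = num / den
    m_pooled = mean_all / w_all
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v_pooled - m_pooled * inv_s_mean) / m_pooled**2
    if mode == "common":
        ok = np.isfinite(alpha) & (m_pooled > 0)
        common = float(alpha[ok].mean()) if ok.any() else _DISP_FLOOR
        return np.full(n_genes, max(common, _DISP_FLOOR))
    if mode == "tagwise":
        return np.where(np.isfinite(alpha), np.maximum(alpha, _DISP_FLOOR), _DISP_FLOOR)
    raise ValueError(f"unknown dispersion mode {mode!r}")


def de_test(
    matrix: pd.DataFrame,
    labels: pd.Series,
    factors: NormalizationFactors,
    p_threshold: float = 0.01,
    fc_threshold: float = 1.5,
    dispersion: str = "common",
) -> pd.DataFrame:
    """Two-group negative-binomial likelihood-ratio test per gene.

    Returns a DataFrame with columns gene, log2fc, pvalue, mean_count and
    passes_filter, one row per gene in input order. log2fc is the normalized
    NRES mean over the normalized RES mean (pseudo-count 0.5 on group means);
    genes with zero counts everywhere get p = 1 and log2fc = 0.
    """
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    lv = sorted(set(labels))
    if set(lv) != {RES, NRES}:
        raise ValueError(f"exactly the two label levels RES/NRES required, got {lv}")
    res_idx = np.flatnonzero((labels == RES).to_numpy())
    nres_idx = np.flatnonzero((labels == NRES).to_numpy())
    if len(res_idx) < 2 or len(nres_idx) < 2:
        raise ValueError("each group needs at least 2 samples")

    y = matrix.to_numpy(dtype=float)
    s = factors.factors.reindex(matrix.columns).to_numpy(dtype=float)

    z = y / s[None, :]
    alpha = _mom_dispersion(z, [res_idx, nres_idx], float(np.mean(1.0 / s)), mode=dispersion)

    q0 = _fit_nb_mean(y, s, alpha)
    q_res = _fit_nb_mean(y[:, res_idx], s[res_idx], alpha)
    q_nres = _fit_nb_mean(y[:, nres_idx], s[nres_idx], alpha)

    mu0 = s[None, :] * q0[:, None]
    ll0 = _nb_loglik(y, mu0, alpha)
    mu1 = np.empty_like(y)
    mu1[:, res_idx] = s[res_idx][None, :] * q_res[:, None]
    mu1[:, nres_idx] = s[nres_idx][None, :] * q_nres[:, None]
    ll1 = _nb_loglik(y, mu1, alpha)

    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)

    mean_res = z[:, res_idx].mean(axis=1)
    mean_nres = z[:, nres_idx].mean(axis=1)
    log2fc = np.log2((mean_nres + _PSEUDO) / (mean_res + _PSEUDO))

    all_zero = y.sum(axis=1) == 0
    pvals = np.where(all_zero, 1.0, pvals)
    log2fc = np.where(all_zero, 0.0, log2fc)

    mean_count = y.mean(axis=1)
    passes = (pvals < p_threshold) & (2.0 ** np.abs(log2fc) > fc_threshold)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "mean_count": mean_count,
            "passes_filter": passes,
        }
    ).reset_index(drop=True)


def _ordered_passing(results: pd.DataFrame) -> pd.DataFrame:
    """Passing genes ordered by ascending p, ties by larger |log2fc| then gene id."""
    out = results.loc[results["passes_filter"]].copy()
    out["_abs_fc"] = -out["log2fc"].abs()
    out = out.sort_values(["pvalue", "_abs_fc", "gene"], kind="mergesort")
    return out.drop(columns="_abs_fc")


def filter_candidates(
    results: pd.DataFrame,
    p_threshold: float = 0.01,
    fc_threshold: float = 1.5,
) -> list[str]:
    """Genes with p < p_threshold and two-sided linear fold change > fc_threshold,
    ordered by ascending p (ties: larger |log2fc|, then gene id)."""
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    res = results.copy()
    res["passes_filter"] = (res["pvalue"] < p_threshold) & (
        2.0 ** res["log2fc"].abs() > fc_threshold
    )
    return _ordered_passing(res)["gene"].tolist()


def select_validation_targets(
    results: pd.DataFrame,
    min_mean_count: float = 50.0,
    top_n: int = 10,
) -> list[str]:
    """Top-n smallest-p candidates whose raw mean count is at least ``min_mean_count``.

    Fewer than ``top_n`` genes are returned when fewer qualify.
    """
    if results.empty:
        raise ValueError("results table is empty")
    passing = _ordered_passing(results)
    passing = passing.loc[passing["mean_count"] >= min_mean_count]
    return passing["gene"].head(top_n).tolist()
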