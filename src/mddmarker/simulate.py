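"""Seeded synthetic datasets with the statistical structure of a two-group
blood transcriptome treatment-response study.

Three generators share one :class:`SimulationConfig`:

* :func:`simulate_counts` — negative-binomial RNA-seq-like count matrices with
  log-normal library-size variation and a planted "signature" of genes whose
  mean is shifted by a configured log2 fold change in non-responders (NRES)
  relative to responders (RES).
* :func:`simulate_qpcr_dataset` — per-gene six-point two-fold dilution series
  (10 down to 0.3125 fM) and duplicate per-sample Cq measurements generated
  from a true standard-curve line plus Gaussian cycle noise.
* :func:`simulate_sighd` — paired pre/post depression-severity scores built so
  that the >= 50% improvement rule recovers the simulated labels exactly.

The default signature is the 19-gene interferon-dominated set with log2 fold
changes between -0.736 and 1.959 that motivates the downstream screening
thresholds (P < 0.01, linear FC > 1.5, mean count >= 50).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import NRES, RES

#: 19-gene default signature: (gene, log2 fold change in NRES vs RES).
DEFAULT_SIGNATURE: tuple[tuple[str, float], ...] = (
    ("OAS3", 0.864),
    ("ISG15", 0.923),
    ("RSAD2", 0.905),
    ("HERC5", 0.795),
    ("IFIT1", 1.161),
    ("SIGLEC1", 1.178),
    ("IFI6", 0.908),
    ("GYPE", -0.6),
    ("IFI44", 0.704),
    ("IFI44L", 0.997),
    ("IFIT3", 0.799),
    ("LRRC2", 0.707),
    ("EPHX1", 0.631),
    ("RAP1GAP", 1.959),
    ("RPS26", 1.012),
    ("OASL", 0.641),
    ("ACCS", -0.736),
    ("MGC70870", -0.731),
    ("SLC14A1", 0.696),
)

#: Six-point two-fold dilution series, in fM.
DILUTION_CONCENTRATIONS_FM: tuple[float, ...] = (10.0, 5.0, 2.5, 1.25, 0.625, 0.3125)

#: qPCR reference gene.
REFERENCE_GENE = "B2M"


class ConfigError(ValueError):
    """A SimulationConfig field violates its constraints."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the discovery cohort: 15 responders vs 15 non-responders,
    2000 genes, a 19-gene planted signature, negative-binomial counts with
    biological coefficient of variation ~0.4 (dispersion 0.16) and 30%
    library-size CV. ``qpcr_noise_sd`` is Gaussian instrument noise on the Cq
    scale, in cycles.
    """

    n_genes: int = 2000
    n_res: int = 15
    n_nres: int = 15
    signature: tuple[tuple[str, float], ...] = DEFAULT_SIGNATURE
    baseline_mean_range: tuple[float, float] = (5.0, 5000.0)
    dispersion: float = 0.16
    libsize_cv: float = 0.3
    qpcr_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_res < 2 or self.n_nres < 2:
            raise ConfigError(
                f"n_res and n_nres must each be >= 2, got {self.n_res}/{self.n_nres}"
            )
        if len(self.signature) > self.n_genes:
            raise ConfigError("signature has more genes than n_genes")
        names = [g for g, _ in self.signature]
        if len(set(names)) != len(names):
            raise ConfigError("signature gene ids must be unique")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigError(f"baseline_mean_range must be a positive interval, got {lo, hi}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if self.libsize_cv < 0:
            raise ConfigError(f"libsize_cv must be >= 0, got {self.libsize_cv}")
        if self.qpcr_noise_sd < 0:
            raise ConfigError(f"qpcr_noise_sd must be >= 0, got {self.qpcr_noise_sd}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def gene_ids(self) -> list[str]:
        sig = [g for g, _ in self.signature]
        n_filler = self.n_genes - len(sig)
        width = max(5, len(str(self.n_genes)))
        return sig + [f"GENE{i:0{width}d}" for i in range(1, n_filler + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"RES{i:02d}" for i in range(1, self.n_res + 1)] + [
            f"NRES{i:02d}" for i in range(1, self.n_nres + 1)
        ]

    @property
    def labels(self) -> pd.Series:
        vals = [RES] * self.n_res + [NRES] * self.n_nres
        return pd.Series(vals, index=self.sample_ids, name="label")


@dataclass(frozen=True)
class GroundTruth:
    informative_genes: frozenset[str]
    effects: dict[str, float]  # per-gene true log2 fold change (NRES vs RES)


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a gene x sample count matrix with a planted group effect.

    Counts are gamma-Poisson (negative binomial) with gene-wise baseline means
    drawn log-uniformly over ``baseline_mean_range``, a single shared
    dispersion, and per-sample log-normal library-size factors. Signature
    genes have their mean multiplied by 2**log2FC in NRES samples only.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    samples = config.sample_ids
    labels = config.labels

    lo, hi = config.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))

    if config.libsize_cv > 0:
        sigma2 = np.log1p(config.libsize_cv**2)
        libfac = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=len(samples)))
    else:
        libfac = np.ones(len(samples))

    lfc = np.zeros(config.n_genes)
    effects: dict[str, float] = {}
    for g, fc in config.signature:
        lfc[genes.index(g)] = fc
        effects[g] = fc

    is_nres = (labels == NRES).to_numpy()
    mean = base[:, None] * libfac[None, :]
    mean = mean * np.where(is_nres[None, :], 2.0 ** lfc[:, None], 1.0)

    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)

    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    truth = GroundTruth(informative_genes=frozenset(effects), effects=effects)
    return matrix, labels, truth


def simulate_sighd(config: SimulationConfig) -> pd.DataFrame:
    """Pre/post depression-severity score pairs consistent with the labels.

    Scores are integers; responders are built with >= 50% improvement and
    non-responders with < 50%, so the labeling rule round-trips exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    labels = config.labels
    n = len(labels)
    pre = rng.integers(14, 29, size=n)
    post = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab == RES:
            improvement = rng.uniform(0.5, 0.95)
            post[i] = int(np.floor(pre[i] * (1 - improvement)))
        else:
            improvement = rng.uniform(0.0, 0.45)
            post[i] = int(np.ceil(pre[i] * (1 - improvement)))
    return pd.DataFrame({"pre": pre, "post": post}, index=labels.index)


def simulate_qpcr_dataset(
    config: SimulationConfig,
    genes: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dilution-series and duplicate sample Cq data for the given genes + B2M.

    Each gene (and the B2M reference) gets a true standard-curve line
    Cq = intercept + slope * log10(concentration) with slope near the perfect
    doubling value -3.32; the dilution series covers the six concentrations
    10, 5, 2.5, 1.25, 0.625 and 0.3125 fM. Per-sample true template
    concentrations are log-normal, with signature effects applied to NRES
    samples, and every sample x gene is measured in duplicate with Gaussian
    noise of ``qpcr_noise_sd`` cycles.

    Returns
    -------
    (dilutions, plate)
        ``dilutions``: long table (gene, concentration_fM, cq).
        ``plate``: long table (sample_id, gene, replicate, cq).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be non-empty")
    known = set(config.gene_ids)
    unknown = [g for g in genes if g not in known]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown}")
    rng = np.random.default_rng(config.seed + 2)
    labels = config.labels
    effects = dict(config.signature)

    all_genes = genes + [REFERENCE_GENE]
    dil_rows = []
    plate_rows = []
    for g in all_genes:
        slope = -3.321928 + rng.normal(0, 0.05)
        intercept = rng.uniform(28.0, 32.0)
        for conc in DILUTION_CONCENTRATIONS_FM:
            cq = intercept + slope * np.log10(conc) + rng.normal(0, config.qpcr_noise_sd)
            dil_rows.append((g, conc, cq))
        if g == REFERENCE_GENE:
            true_conc = np.exp(rng.normal(np.log(6.0), 0.15, size=len(labels)))
        else:
            true_conc = np.exp(rng.normal(np.log(1.5), 0.4, size=len(labels)))
            fc = effects.get(g, 0.0)
            true_conc = true_conc * np.where(labels.to_numpy() == NRES, 2.0**fc, 1.0)
        for s, conc in zip(labels.index, true_conc):
            for rep in (1, 2):
                cq = intercept + slope * np.log10(conc) + rng.normal(0, config.qpcr_noise_sd)
                plate_rows.append((s, g, rep, cq))
    dilutions = pd.DataFrame(dil_rows, columns=["gene", "concentration_fM", "cq"])
    plate = pd.DataFrame(plate_rows, columns=["sample_id", "gene", "replicate", "cq"])
    return dilutions, plate
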