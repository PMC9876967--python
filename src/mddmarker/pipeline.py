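"""End-to-end orchestration: simulate → screen → qPCR → select → classify.

File formats
------------
* Count matrix: TSV, header row = sample ids, first column = gene id.
* Labels: two-column TSV (sample_id, label in {RES, NRES}).
* qPCR plate: long TSV (sample_id, gene, replicate, cq); dilution series TSV
  (gene, concentration_fM, cq).
* Discrete Bayes model: JSON (cut points, counts, epsilon, classes).

Responder labeling follows the >= 50% rule: a participant whose
depression-severity score improves by at least half of the pre-treatment
score is a responder (RES), otherwise a non-responder (NRES).

A test-set firewall is enforced by instrumentation: every stage records which
dataset (train/test) it reads into an :class:`AccessLog`, and the run report
lists any access to test data before the classification stage (there are
none; the check exists so this stays true under modification). The test
cohort's qPCR ratios are anchored to the *training* responders' mean so that
no test label is consulted before classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import bayes, de, qpcr, selection, simulate
from .metrics import NRES, RES, compute_metrics, confusion

logger = logging.getLogger("mddmarker")


# ---------------------------------------------------------------- labeling

@dataclass(frozen=True)
class SighdRecord:
    sample_id: str
    pre: float
    post: float


def label_response(record: SighdRecord) -> str:
    """RES iff the score improved by at least 50% of the pre-treatment score."""
    if record.pre <= 0:
        raise ValueError(
            f"sample {record.sample_id!r}: pre-treatment score must be > 0, got {record.pre}"
        )
    improvement = (record.pre - record.post) / record.pre
    return RES if improvement >= 0.5 else NRES


def label_scores(scores: pd.DataFrame) -> pd.Series:
    """Apply :func:`label_response` to a (pre, post) table indexed by sample id."""
    out = {
        str(sid): label_response(SighdRecord(str(sid), row["pre"], row["post"]))
        for sid, row in scores.iterrows()
    }
    return pd.Series(out, name="label")


# ---------------------------------------------------------------- file I/O

class ParseError(ValueError):
    pass


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dup_samples = sorted({s for s in samples if samples.count(s) > 1})
    if dup_samples:
        raise ParseError(f"{path}: duplicate sample ids {dup_samples}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise ParseError(f"{path}: cannot parse matrix TSV: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dup}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        for c in non_numeric:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()]
            line = int(df.index.get_loc(bad.index[0])) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: non-numeric cell in column {c!r} near line {line}")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["sample_id", "label"]:
        raise ParseError(f"{path}: expected columns sample_id, label, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample id(s) {dup}")
    bad = df.loc[~df["label"].isin([RES, NRES])]
    if len(bad):
        raise ParseError(f"{path}: invalid label(s) {bad['label'].unique().tolist()}")
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"].astype(str), name="label")


def write_model(model: bayes.DiscreteBayesModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def read_model(path: str | Path) -> bayes.DiscreteBayesModel:
    return bayes.DiscreteBayesModel.from_json(Path(path).read_text())


# ---------------------------------------------------------------- firewall

@dataclass
class AccessLog:
    """Stage-by-stage record of which dataset each stage read."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, dataset: str) -> None:
        self.entries.append({"stage": stage, "dataset": dataset})

    def violations(self, classify_stage: str = "classify") -> list[dict]:
        """Test-data accesses logged before the classification stage began."""
        out = []
        seen_classify = False
        for e in self.entries:
            if e["stage"] == classify_stage:
                seen_classify = True
            if e["dataset"] == "test" and not seen_classify:
                out.append(e)
        return out


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_genes: int = 2000
    n_res_train: int = 15
    n_nres_train: int = 15
    n_res_test: int = 22
    n_nres_test: int = 12
    dispersion: float = 0.16
    libsize_cv: float = 0.3
    qpcr_noise_sd: float = 0.15
    p_threshold: float = 0.01
    fc_threshold: float = 1.5
    min_mean_count: float = 50.0
    top_n: int = 10
    qpcr_alpha: float = 0.05
    max_markers: int = 8
    divisions: int = 2
    epsilon: float = 0.5
    conditional: str = "cross_marker"
    criterion_mode: str = "sensitivity_with_specificity_floor"
    specificity_floor: float = 0.5
    ks: tuple[int, ...] = (2, 3)

    def validate(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.divisions < 2:
            raise ValueError("divisions must be >= 2")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.conditional not in ("cross_marker", "per_marker"):
            raise ValueError(f"unknown conditional {self.conditional!r}")
        if self.criterion_mode not in ("sensitivity_with_specificity_floor", "f1"):
            raise ValueError(f"unknown criterion mode {self.criterion_mode!r}")
        if any(k < 2 for k in self.ks):
            raise ValueError("combination sizes must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ks" in raw:
            raw["ks"] = tuple(raw["ks"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate → screen → qPCR validation → marker selection → test classification.

    Returns the run report (also written to ``<out_dir>/report.json``); all
    randomness derives from ``config.seed``, so a fixed config reproduces the
    report byte-identically.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = AccessLog()
    rep: dict = {"parameters": asdict(config), "stages": []}

    # --- simulate -----------------------------------------------------
    train_cfg = simulate.SimulationConfig(
        n_genes=config.n_genes,
        n_res=config.n_res_train,
        n_nres=config.n_nres_train,
        dispersion=config.dispersion,
        libsize_cv=config.libsize_cv,
        qpcr_noise_sd=config.qpcr_noise_sd,
        seed=config.seed,
    )
    test_cfg = simulate.SimulationConfig(
        n_genes=config.n_genes,
        n_res=config.n_res_test,
        n_nres=config.n_nres_test,
        dispersion=config.dispersion,
        libsize_cv=config.libsize_cv,
        qpcr_noise_sd=config.qpcr_noise_sd,
        seed=config.seed + 1_000_003,
    )
    logger.info("simulate: training %d+%d, test %d+%d, %d genes, seed %d",
                train_cfg.n_res, train_cfg.n_nres, test_cfg.n_res, test_cfg.n_nres,
                config.n_genes, config.seed)
    matrix, train_labels, truth = simulate.simulate_counts(train_cfg)
    train_scores = simulate.simulate_sighd(train_cfg)
    train_labels = label_scores(train_scores).reindex(train_labels.index)
    rep["stages"].append({"stage": "simulate", "seed": config.seed})
    write_matrix(matrix, out / "train_counts.tsv")
    write_labels(train_labels, out / "train_labels.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps({"informative_genes": sorted(truth.informative_genes),
                    "effects": truth.effects}, indent=2)
    )
    log.record("simulate", "train")

    # --- DE screen ----------------------------------------------------
    log.record("screen", "train")
    factors = de.compute_tmm_factors(matrix)
    results = de.de_test(matrix, train_labels, factors,
                         p_threshold=config.p_threshold, fc_threshold=config.fc_threshold)
    results.to_csv(out / "de_results.tsv", sep="\t", index=False)
    candidates = de.filter_candidates(results, config.p_threshold, config.fc_threshold)
    targets = de.select_validation_targets(results, config.min_mean_count, config.top_n)
    logger.info("screen: %d candidates, %d validation targets", len(candidates), len(targets))
    rep["stages"].append({
        "stage": "screen",
        "n_candidates": len(candidates),
        "validation_targets": targets,
        "reference_sample": factors.reference_sample,
    })
    if not targets:
        raise RuntimeError("screen stage produced no validation targets")

    # --- qPCR validation (training cohort) ----------------------------
    log.record("qpcr", "train")
    dilutions, train_plate = simulate.simulate_qpcr_dataset(train_cfg, targets)
    dilutions.to_csv(out / "dilution_series.tsv", sep="\t", index=False)
    train_plate.to_csv(out / "train_plate.tsv", sep="\t", index=False)
    curves = {
        g: qpcr.fit_standard_curve(
            qpcr.DilutionSeries(
                gene=g,
                concentrations_fM=grp["concentration_fM"].to_numpy(),
                cq=grp["cq"].to_numpy(),
            )
        )
        for g, grp in dilutions.groupby("gene", sort=False)
    }
    quantities = qpcr.quantify_plate(train_plate, curves)
    fc = qpcr.fold_changes(
        quantities.drop(columns=simulate.REFERENCE_GENE),
        quantities[simulate.REFERENCE_GENE],
        train_labels,
    )
    fc.to_csv(out / "train_fold_changes.tsv", sep="\t", index_label="sample_id")
    stats_table = qpcr.compare_groups(fc, train_labels)
    stats_table.to_csv(out / "qpcr_stats.tsv", sep="\t", index=False)
    ordered = stats_table.sort_values("p", kind="mergesort")
    markers = ordered.loc[ordered["p"] < config.qpcr_alpha, "gene"].tolist()
    markers = markers[: config.max_markers]
    fallback = False
    if len(markers) < max(config.ks):
        # too few significant genes to form combinations: top up with the
        # next-smallest p-values so selection can still run, and flag it
        fallback = True
        markers = ordered["gene"].head(max(config.ks)).tolist()
    logger.info("qpcr: %d markers of %d targets%s", len(markers), len(targets),
                " (topped up past the significance gate)" if fallback else "")
    rep["stages"].append({"stage": "qpcr", "markers": markers, "significance_fallback": fallback})
    if len(markers) < max(config.ks):
        raise RuntimeError(
            f"only {len(markers)} qPCR markers available; "
            f"need at least {max(config.ks)} for selection"
        )

    # --- marker selection (training only) -----------------------------
    log.record("select", "train")
    clf_cfg = selection.ClassifierConfig(
        divisions=config.divisions,
        epsilon=config.epsilon,
        conditional=config.conditional,  # type: ignore[arg-type]
    )
    criterion = selection.SelectionCriterion(
        mode=config.criterion_mode,  # type: ignore[arg-type]
        specificity_floor=config.specificity_floor,
    )
    train_values = fc[markers]
    selections: dict[int, selection.SelectionResult] = {}
    for k in config.ks:
        sel = selection.loo_select(train_values, train_labels, markers, k, criterion, clf_cfg)
        selections[k] = sel
        logger.info("select k=%d: winner %s", k, ",".join(sel.winner))
    (out / "selection.json").write_text(
        json.dumps({str(k): s.to_jsonable() for k, s in selections.items()}, indent=2)
    )
    rep["stages"].append({
        "stage": "select",
        "winners": {str(k): list(s.winner) for k, s in selections.items()},
    })

    # --- classify the held-out test cohort ----------------------------
    log.record("classify", "test")
    test_scores = simulate.simulate_sighd(test_cfg)
    test_labels = label_scores(test_scores)
    write_labels(test_labels, out / "test_labels.tsv")
    # the test cohort runs its own calibration curves (absolute quantification
    # is per-run: the dilution standards ship with the plate)
    test_dil, test_plate = simulate.simulate_qpcr_dataset(test_cfg, targets)
    test_plate.to_csv(out / "test_plate.tsv", sep="\t", index=False)
    test_curves = {
        g: qpcr.fit_standard_curve(
            qpcr.DilutionSeries(
                gene=g,
                concentrations_fM=grp["concentration_fM"].to_numpy(),
                cq=grp["cq"].to_numpy(),
            )
        )
        for g, grp in test_dil.groupby("gene", sort=False)
    }
    test_quant = qpcr.quantify_plate(test_plate, test_curves)
    test_ratio = test_quant.drop(columns=simulate.REFERENCE_GENE).div(
        test_quant[simulate.REFERENCE_GENE], axis=0
    )
    # anchor by TRAINING responders' mean ratio: no test labels involved
    train_ratio = quantities.drop(columns=simulate.REFERENCE_GENE).div(
        quantities[simulate.REFERENCE_GENE], axis=0
    )
    anchor = train_ratio.loc[train_labels == RES].mean(axis=0)
    test_values = test_ratio.div(anchor, axis=1)[markers]

    table3 = {}
    for k, sel in selections.items():
        combo = list(sel.winner)
        scheme = bayes.fit_discretization(train_values[combo], config.divisions)
        model = bayes.fit_model(
            bayes.discretize_frame(scheme, train_values[combo]),
            train_labels, scheme, config.epsilon, config.conditional,  # type: ignore[arg-type]
        )
        write_model(model, out / f"model_k{k}.json")
        train_pred = bayes.classify_frame(model, bayes.discretize_frame(scheme, train_values[combo]))
        test_pred = bayes.classify_frame(model, bayes.discretize_frame(scheme, test_values[combo]))
        test_pred.to_csv(out / f"test_predictions_k{k}.tsv", sep="\t", index_label="sample_id")
        m_train = compute_metrics(
            confusion(train_pred["label"].to_dict(), train_labels.to_dict())
        )
        m_test = compute_metrics(
            confusion(test_pred["label"].to_dict(), test_labels.to_dict())
        )
        table3[str(k)] = {
            "combination": combo,
            "training_resubstitution": m_train.rounded(),
            "test": m_test.rounded(),
            "test_raw": {
                "accuracy": m_test.accuracy,
                "sensitivity": m_test.sensitivity,
                "specificity": m_test.specificity,
                "precision": m_test.precision,
                "f1": m_test.f1,
            },
        }
    rep["stages"].append({"stage": "classify", "metrics": table3})
    rep["metrics"] = table3
    rep["ground_truth_informative"] = sorted(truth.informative_genes)
    rep["firewall"] = {
        "access_log": log.entries,
        "violations": log.violations(),
    }
    (out / "report.json").write_text(json.dumps(rep, indent=2, sort_keys=True))
    logger.info("report written to %s", out / "report.json")
    return rep
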