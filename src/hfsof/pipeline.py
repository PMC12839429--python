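"""End-to-end orchestration of the three pipeline phases.

Phase 1 embeds standardized features with kernel PCA; Phase 2 prunes the
embedding with the filter ensemble followed by scatter-difference
thresholding; Phase 3 runs the wrapper optimizer and trains/evaluates the
final SVM. Each phase also reports held-out SVM metrics on its own feature
set so the phase-by-phase comparison is reproducible on any dataset.

A single master seed fans out deterministically to the split, fold and
optimizer seeds. Timings are logged and written separately from the
manifest so repeated runs with one seed produce byte-identical manifests.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from hfsof._version import __version__ as _pkg_version
from hfsof.eval_metrics import MetricsReport, evaluate_classifier, fit_final_svm
from hfsof.filter_ensemble import (
    FILTER_MODES,
    FilterRankTable,
    build_rank_table,
    select_candidate_pool,
)
from hfsof.kpca import KpcaModel, fit_kpca, training_embedding, transform_kpca
from hfsof.msdlda import MsdldaResult, run_msdlda
from hfsof.preprocess_io import (
    Dataset,
    StandardizationModel,
    apply_standardizer,
    fit_standardizer,
    load_feature_table,
    load_image_dataset,
    stratified_split,
    to_feature_dataset,
)
from hfsof.wma_wrapper import FitnessSpec, SearchTrace, run_pso, run_wma

logger = logging.getLogger(__name__)

OPTIMIZERS = ("wma", "pso")
KPCA_MODES = ("rbf", "skip")


@dataclass
class PipelineConfig:
    """Resolved run configuration; defaults mirror the reference settings."""

    input_path: str | None = None
    input_type: str = "table"            # "table" | "images"
    image_size: tuple[int, int] = (64, 64)
    label_column: str = "label"
    delimiter: str = ","

    test_fraction: float = 0.3
    kpca_p: int = 1000
    kpca_gamma: float | str = "1/d"      # "1/d" or an explicit float
    kpca_mode: str = "rbf"               # "skip" bypasses the embedding
    filter_bins: int = 10
    filter_mode: str = "fusion_median"
    pool_size: int | None = None         # default ceil(p / 2)
    alpha: float = 0.05
    optimizer: str = "wma"
    pop_size: int = 45
    iterations: int = 100
    svm_c: float = 100.0
    svm_gamma: float = 0.01
    k_fold: int = 3
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; valid: {OPTIMIZERS}"
            )
        if self.kpca_mode not in KPCA_MODES:
            raise ValueError(
                f"unknown kpca mode {self.kpca_mode!r}; valid: {KPCA_MODES}"
            )
        if self.filter_mode not in FILTER_MODES:
            raise ValueError(
                f"unknown filter mode {self.filter_mode!r}; valid: {FILTER_MODES}"
            )

    # --- seeds -----------------------------------------------------------
    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.master_seed).generate_state(3)
        return {
            "split": int(state[0] % (2**31)),
            "folds": int(state[1] % (2**31)),
            "optimizer": int(state[2] % (2**31)),
        }

    # --- (de)serialization ----------------------------------------------
    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        mapping = {
            ("input", "path"): "input_path",
            ("input", "type"): "input_type",
            ("input", "image_size"): "image_size",
            ("input", "label_column"): "label_column",
            ("input", "delimiter"): "delimiter",
            ("split", "test_fraction"): "test_fraction",
            ("split", "seed"): None,  # folded into master seed handling
            ("kpca", "p"): "kpca_p",
            ("kpca", "gamma"): "kpca_gamma",
            ("kpca", "mode"): "kpca_mode",
            ("filters", "bins"): "filter_bins",
            ("filters", "mode"): "filter_mode",
            ("filters", "pool_size"): "pool_size",
            ("msdlda", "alpha"): "alpha",
            ("optimizer", "name"): "optimizer",
            ("optimizer", "pop_size"): "pop_size",
            ("optimizer", "iterations"): "iterations",
            ("svm", "C"): "svm_c",
            ("svm", "gamma"): "svm_gamma",
            ("fitness", "k_fold"): "k_fold",
            ("output", "dir"): "output_dir",
        }
        for (section, key), attr in mapping.items():
            if section in data and isinstance(data[section], dict) and key in data[section]:
                if attr is not None:
                    value = data[section][key]
                    if attr == "image_size" and value is not None:
                        value = tuple(value)
                    setattr(cfg, attr, value)
        if "seed" in data:
            cfg.master_seed = int(data["seed"])
        cfg.__post_init__()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "input": {
                "path": self.input_path,
                "type": self.input_type,
                "image_size": list(self.image_size),
                "label_column": self.label_column,
                "delimiter": self.delimiter,
            },
            "split": {"test_fraction": self.test_fraction},
            "kpca": {"p": self.kpca_p, "gamma": self.kpca_gamma, "mode": self.kpca_mode},
            "filters": {
                "bins": self.filter_bins,
                "mode": self.filter_mode,
                "pool_size": self.pool_size,
            },
            "msdlda": {"alpha": self.alpha},
            "optimizer": {
                "name": self.optimizer,
                "pop_size": self.pop_size,
                "iterations": self.iterations,
            },
            "svm": {"C": self.svm_c, "gamma": self.svm_gamma},
            "fitness": {"k_fold": self.k_fold},
            "seed": self.master_seed,
            "output": {"dir": self.output_dir},
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    standardizer: StandardizationModel
    kpca_model: KpcaModel | None
    rank_table: FilterRankTable
    msdlda_result: MsdldaResult
    trace: SearchTrace
    pool_indices: np.ndarray        # embedding-space indices of the candidate pool
    s0_indices: np.ndarray          # embedding-space indices surviving thresholding
    selected_indices: np.ndarray    # embedding-space indices of the final subset
    reports: dict[str, MetricsReport]
    manifest: dict[str, Any]
    final_classifier: Any = None
    Z_train: np.ndarray | None = None
    train_labels: np.ndarray | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _load_input(config: PipelineConfig) -> Dataset:
    if config.input_path is None:
        raise ValueError("config has no input path and no dataset was supplied")
    if config.input_type == "images":
        raw = load_image_dataset(config.input_path, config.image_size)
        return to_feature_dataset(raw)
    return load_feature_table(
        config.input_path, label_column=config.label_column, delimiter=config.delimiter
    )


def _resolve_gamma(config: PipelineConfig, d: int) -> float:
    if config.kpca_gamma == "1/d":
        return 1.0 / d
    return float(config.kpca_gamma)


def run_pipeline(
    config: PipelineConfig, dataset: Dataset | None = None
) -> PipelineResult:
    """Run all three phases and (optionally) write the artifact set."""
    seeds = config.stage_seeds()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    ds = dataset if dataset is not None else _load_input(config)
    train_raw, test_raw = stratified_split(ds, config.test_fraction, seeds["split"])
    standardizer = fit_standardizer(train_raw)
    train = apply_standardizer(standardizer, train_raw)
    test = apply_standardizer(standardizer, test_raw)
    timings["preprocess"] = time.perf_counter() - t0
    logger.info(
        "preprocess: N_train=%d N_test=%d M=%d C=%d",
        train.n_samples, test.n_samples, train.n_features, train.n_classes,
    )

    # ---- Phase 1: embedding --------------------------------------------
    t0 = time.perf_counter()
    if config.kpca_mode == "rbf":
        gamma = _resolve_gamma(config, train.n_features)
        kpca_model = fit_kpca(train.X, config.kpca_p, gamma=gamma)
        Z_train = training_embedding(kpca_model).Z
        Z_test = transform_kpca(kpca_model, test.X).Z
    else:
        kpca_model = None
        Z_train = train.X
        Z_test = test.X
    p = Z_train.shape[1]
    timings["phase1"] = time.perf_counter() - t0
    logger.info("phase1: embedded to p=%d components", p)

    reports: dict[str, MetricsReport] = {}
    reports["phase1"] = _phase_report(config, Z_train, train.y, Z_test, test.y,
                                      ds.n_classes, ds.class_names)

    # ---- Phase 2: filter ensemble + thresholding -----------------------
    t0 = time.perf_counter()
    rank_table = build_rank_table(
        Z_train, train.y, n_bins=config.filter_bins, mode=config.filter_mode
    )
    pool_size = config.pool_size if config.pool_size is not None else math.ceil(p / 2)
    pool_size = min(pool_size, p)
    pool = select_candidate_pool(rank_table.r_fused, pool_size)
    msdlda_result = run_msdlda(Z_train[:, pool], train.y, config.alpha)
    s0 = pool[msdlda_result.selected]
    timings["phase2"] = time.perf_counter() - t0
    logger.info("phase2: pool=%d |S0|=%d", pool_size, s0.shape[0])

    reports["phase2"] = _phase_report(config, Z_train[:, s0], train.y,
                                      Z_test[:, s0], test.y,
                                      ds.n_classes, ds.class_names)

    # ---- Phase 3: wrapper optimization ---------------------------------
    t0 = time.perf_counter()
    spec = FitnessSpec(
        X=Z_train[:, s0],
        y=train.y,
        svm_c=config.svm_c,
        svm_gamma=config.svm_gamma,
        k_fold=config.k_fold,
        fold_seed=seeds["folds"],
    )
    optimize = run_wma if config.optimizer == "wma" else run_pso
    trace = optimize(spec, config.pop_size, config.iterations, seeds["optimizer"])
    selected = s0[np.flatnonzero(trace.best_mask)]
    timings["phase3_search"] = time.perf_counter() - t0
    logger.info(
        "phase3: |S*|=%d best CV fitness=%.4f (%d evaluations, %d cache hits)",
        selected.shape[0], trace.best_fitness_final,
        trace.n_evaluations, trace.n_cache_hits,
    )

    t0 = time.perf_counter()
    classifier = fit_final_svm(Z_train[:, selected], train.y,
                               C_svm=config.svm_c, gamma_svm=config.svm_gamma)
    reports["phase3"] = evaluate_classifier(
        classifier, Z_test[:, selected], test.y, ds.n_classes, ds.class_names
    )
    timings["phase3_eval"] = time.perf_counter() - t0

    manifest = {
        "software_version": _pkg_version,
        "config": config.to_dict(),
        "seeds": seeds,
        "n_train": int(train.n_samples),
        "n_test": int(test.n_samples),
        "feature_counts": {
            "input": int(train.n_features),
            "embedding_p": int(p),
            "pool": int(pool_size),
            "s0": int(s0.shape[0]),
            "selected": int(selected.shape[0]),
        },
        "best_cv_fitness": round(trace.best_fitness_final, 6),
        "selected_indices": [int(j) for j in selected],
        "artifacts": {},
    }

    result = PipelineResult(
        config=config,
        standardizer=standardizer,
        kpca_model=kpca_model,
        rank_table=rank_table,
        msdlda_result=msdlda_result,
        trace=trace,
        pool_indices=pool,
        s0_indices=s0,
        selected_indices=selected,
        reports=reports,
        manifest=manifest,
        final_classifier=classifier,
        Z_train=Z_train[:, selected],
        train_labels=train.y,
        timings=timings,
    )
    if config.output_dir is not None:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _phase_report(
    config: PipelineConfig,
    Z_train: np.ndarray,
    y_train: np.ndarray,
    Z_test: np.ndarray,
    y_test: np.ndarray,
    n_classes: int,
    class_names: list[str],
) -> MetricsReport:
    clf = fit_final_svm(Z_train, y_train, C_svm=config.svm_c, gamma_svm=config.svm_gamma)
    return evaluate_classifier(clf, Z_test, y_test, n_classes, class_names)


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rank_table": out_dir / "rank_table.tsv",
        "msdlda_table": out_dir / "msdlda_table.tsv",
        "trace": out_dir / "trace.tsv",
        "selected_indices": out_dir / "selected_indices.json",
        "metrics_phase1": out_dir / "metrics_phase1.json",
        "metrics_phase2": out_dir / "metrics_phase2.json",
        "metrics_phase3": out_dir / "metrics_phase3.json",
        "confusion_phase3": out_dir / "confusion_phase3.tsv",
        "manifest": out_dir / "manifest.json",
        "timings": out_dir / "timings.json",
    }
    result.rank_table.save(paths["rank_table"])
    result.msdlda_result.save(paths["msdlda_table"])
    result.trace.save(paths["trace"])
    with open(paths["selected_indices"], "w") as fh:
        json.dump([int(j) for j in result.selected_indices], fh)
        fh.write("\n")
    for phase in ("phase1", "phase2", "phase3"):
        result.reports[phase].to_json(paths[f"metrics_{phase}"])
    cm = result.reports["phase3"].confusion
    if cm is not None:
        cm.save(paths["confusion_phase3"])
    result.manifest["artifacts"] = {k: str(v) for k, v in paths.items() if k != "manifest"}
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    # timings are deliberately kept out of the manifest: they vary run to run
    with open(paths["timings"], "w") as fh:
        json.dump({k: round(v, 3) for k, v in result.timings.items()}, fh, indent=2)
        fh.write("\n")


GRID_KEYS = {
    "filter_mode": FILTER_MODES,
    "alpha": None,
    "optimizer": OPTIMIZERS,
}


def run_ablation_grid(
    config: PipelineConfig,
    grid: dict[str, list],
    dataset: Dataset | None = None,
) -> pd.DataFrame:
    """Run the experiment grid over filter mode, alpha and optimizer.

    The preprocessing and Phase-1 embedding are computed once and reused by
    every cell. Returns one row per cell with macro and weighted metrics of
    that cell's final (Phase-3) report.
    """
    for key, values in grid.items():
        if key not in GRID_KEYS:
            raise ValueError(
                f"unknown grid switch {key!r}; valid: {sorted(GRID_KEYS)}"
            )
        allowed = GRID_KEYS[key]
        if allowed is not None:
            bad = [v for v in values if v not in allowed]
            if bad:
                raise ValueError(f"invalid values {bad} for {key!r}; valid: {allowed}")

    seeds = config.stage_seeds()
    ds = dataset if dataset is not None else _load_input(config)
    train_raw, test_raw = stratified_split(ds, config.test_fraction, seeds["split"])
    standardizer = fit_standardizer(train_raw)
    train = apply_standardizer(standardizer, train_raw)
    test = apply_standardizer(standardizer, test_raw)
    if config.kpca_mode == "rbf":
        gamma = _resolve_gamma(config, train.n_features)
        kpca_model = fit_kpca(train.X, config.kpca_p, gamma=gamma)
        Z_train = training_embedding(kpca_model).Z
        Z_test = transform_kpca(kpca_model, test.X).Z
    else:
        Z_train, Z_test = train.X, test.X
    p = Z_train.shape[1]

    from itertools import product

    keys = sorted(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        filter_mode = overrides.get("filter_mode", config.filter_mode)
        alpha = overrides.get("alpha", config.alpha)
        optimizer = overrides.get("optimizer", config.optimizer)

        rank_table = build_rank_table(
            Z_train, train.y, n_bins=config.filter_bins, mode=filter_mode
        )
        pool_size = config.pool_size if config.pool_size is not None else math.ceil(p / 2)
        pool_size = min(pool_size, p)
        pool = select_candidate_pool(rank_table.r_fused, pool_size)
        msd = run_msdlda(Z_train[:, pool], train.y, alpha)
        s0 = pool[msd.selected]

        spec = FitnessSpec(
            X=Z_train[:, s0], y=train.y, svm_c=config.svm_c,
            svm_gamma=config.svm_gamma, k_fold=config.k_fold,
            fold_seed=seeds["folds"],
        )
        optimize = run_wma if optimizer == "wma" else run_pso
        trace = optimize(spec, config.pop_size, config.iterations, seeds["optimizer"])
        selected = s0[np.flatnonzero(trace.best_mask)]
        clf = fit_final_svm(Z_train[:, selected], train.y,
                            C_svm=config.svm_c, gamma_svm=config.svm_gamma)
        report = evaluate_classifier(clf, Z_test[:, selected], test.y,
                                     ds.n_classes, ds.class_names)
        rows.append(
            {
                "filter_mode": filter_mode,
                "alpha": alpha,
                "optimizer": optimizer,
                "n_s0": int(s0.shape[0]),
                "n_selected": int(selected.shape[0]),
                "best_cv_fitness": trace.best_fitness_final,
                "accuracy": report.accuracy,
                "macro_precision": report.macro["precision"],
                "macro_recall": report.macro["recall"],
                "macro_f1": report.macro["f1"],
                "macro_auc": report.macro["auc"],
                "weighted_precision": report.weighted["precision"],
                "weighted_recall": report.weighted["recall"],
                "weighted_f1": report.weighted["f1"],
                "weighted_auc": report.weighted["auc"],
            }
        )
    return pd.DataFrame(rows)


def evaluate_on(result: PipelineResult, ds: Dataset) -> MetricsReport:
    """Apply a fitted pipeline to a new dataset and report metrics."""
    standardized = apply_standardizer(result.standardizer, ds)
    if result.kpca_model is not None:
        Z = transform_kpca(result.kpca_model, standardized.X).Z
    else:
        Z = standardized.X
    return evaluate_classifier(
        result.final_classifier,
        Z[:, result.selected_indices],
        ds.y,
        ds.n_classes,
        ds.class_names,
    )
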