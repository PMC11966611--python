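"""Experiment orchestration: cross-validated runs, the 2x2 ablation, a-sweeps.

An experiment is fully described by a config (data source, split, sampler,
loss, model, train sections); every stochastic stage carries its own seed,
so an experiment directory containing the config and the split plan is
sufficient to reproduce every number exactly. Ablation cells share data,
splits, and model seeds — only the sampler strategy and loss differ.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    DrugResponseTable,
    JoinedDataset,
    MoaMap,
    assemble_dataset,
    read_feature_matrix,
    read_moa_map,
    read_response_table,
)
from .evaluation import (
    MetricsReport,
    aggregate_folds,
    attach_moa,
    groupwise_metrics,
    improvement_deltas,
)
from .loss import LossConfig
from .sampling import SamplerConfig
from .splitting import (
    SplitPlan,
    drug_blind_folds,
    random_pair_folds,
    validate_plan,
    validation_holdout,
    write_plan,
)
from .synthetic import SyntheticSpec, generate_dataset
from .training import (
    FCNNRegressor,
    ModelConfig,
    Standardizer,
    TrainConfig,
    train_model,
)

logger = logging.getLogger(__name__)

DEFAULT_SWEEP_GRID = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass
class SplitConfig:
    mode: str = "drug_blind"
    k: int = 10
    seed: int = 0
    validation_fraction: float = 0.2


@dataclass
class ExperimentConfig:
    data: dict[str, Any]
    split: SplitConfig = field(default_factory=SplitConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    model: dict[str, Any] = field(default_factory=dict)
    train: TrainConfig = field(default_factory=TrainConfig)
    min_group_size: int = 2
    sweep_grid: tuple[float, ...] = DEFAULT_SWEEP_GRID


def load_experiment_config(source: str | Path | dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file or an equivalent dict."""
    raw = (
        dict(source)
        if isinstance(source, dict)
        else yaml.safe_load(Path(source).read_text())
    )
    sampler_raw = dict(raw.get("sampler", {}))
    if "lambda" in sampler_raw:
        sampler_raw["mixing_weight"] = sampler_raw.pop("lambda")
    loss_raw = dict(raw.get("loss", {}))
    loss_cfg = LossConfig(
        loss_kind=loss_raw.get("kind", "moorle"),
        regularization_weight=float(loss_raw.get("a", 1.0)),
    )
    model_raw = dict(raw.get("model", {}))
    if "hidden_layer_sizes" in model_raw:
        model_raw["hidden_layer_sizes"] = tuple(model_raw["hidden_layer_sizes"])
    sweep_raw = raw.get("sweep", {})
    return ExperimentConfig(
        data=dict(raw.get("data", {})),
        split=SplitConfig(**raw.get("split", {})),
        sampler=SamplerConfig(**sampler_raw),
        loss=loss_cfg,
        model=model_raw,
        train=TrainConfig(**raw.get("train", {})),
        min_group_size=int(raw.get("min_group_size", 2)),
        sweep_grid=tuple(sweep_raw.get("a_values", DEFAULT_SWEEP_GRID)),
    )


def load_data(
    data: dict[str, Any],
) -> tuple[JoinedDataset, DrugResponseTable, MoaMap | None]:
    """Materialize the dataset from a config ``data`` section.

    Either ``synthetic: {<SyntheticSpec fields>}`` or ``paths: {responses,
    sample_features, drug_features[, moa]}``.
    """
    if "synthetic" in data:
        spec = SyntheticSpec(**data["synthetic"])
        samples, drugs, table, moa, _ = generate_dataset(spec)
        return assemble_dataset(table, samples, drugs), table, moa
    if "paths" in data:
        paths = data["paths"]
        table = read_response_table(paths["responses"])
        samples = read_feature_matrix(paths["sample_features"])
        drugs = read_feature_matrix(paths["drug_features"])
        moa = read_moa_map(paths["moa"]) if "moa" in paths else None
        return assemble_dataset(table, samples, drugs), table, moa
    raise ValueError("data section needs either 'synthetic' or 'paths'")


def make_plan(table: DrugResponseTable, split: SplitConfig) -> SplitPlan:
    if split.mode == "drug_blind":
        plan = drug_blind_folds(table, split.k, split.seed)
    elif split.mode == "random_pair":
        plan = random_pair_folds(table, split.k, split.seed)
    else:
        raise ValueError(f"unknown split mode {split.mode!r}")
    violations = validate_plan(plan, table)
    if violations:
        raise RuntimeError(f"generated split plan failed validation: {violations}")
    return plan


def _fit_fold_model(
    dataset: JoinedDataset,
    train_idx: np.ndarray,
    sampler: SamplerConfig,
    loss: LossConfig,
    model_kwargs: dict,
    train_cfg: TrainConfig,
    fold: int,
    val_idx: np.ndarray | None = None,
) -> tuple[FCNNRegressor, Standardizer, list[dict]]:
    """Standardize on the training portion, train a fresh seeded model."""
    scaler = Standardizer().fit(dataset.features[train_idx])
    X = scaler.transform(dataset.features)
    kwargs = dict(model_kwargs)
    base_seed = kwargs.pop("seed", 0)
    model = FCNNRegressor(
        ModelConfig(input_dim=dataset.input_dim, seed=base_seed * 1009 + fold, **kwargs)
    )
    fold_sampler = SamplerConfig(
        strategy=sampler.strategy,
        batch_size=sampler.batch_size,
        mixing_weight=sampler.mixing_weight,
        seed=sampler.seed * 1009 + fold,
    )
    fold_train = TrainConfig(
        epochs=train_cfg.epochs,
        learning_rate=train_cfg.learning_rate,
        optimizer=train_cfg.optimizer,
        early_stop_patience=train_cfg.early_stop_patience,
        seed=train_cfg.seed * 1009 + fold,
    )
    result = train_model(
        model,
        X,
        dataset.responses,
        dataset.groups,
        train_idx,
        fold_sampler,
        loss,
        fold_train,
        val_indices=val_idx,
    )
    return model, scaler, result.history


def evaluate_fold(
    model: FCNNRegressor,
    scaler: Standardizer,
    dataset: JoinedDataset,
    test_idx: np.ndarray,
    moa: MoaMap | None,
    min_group_size: int = 2,
) -> MetricsReport:
    preds = model.predict(scaler.transform(dataset.features[test_idx]))
    report = groupwise_metrics(
        dataset.responses[test_idx],
        preds,
        dataset.groups[test_idx],
        min_group_size=min_group_size,
    )
    if moa is not None:
        report = attach_moa(report, moa)
    return report


def run_cv_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    dataset: JoinedDataset | None = None,
    table: DrugResponseTable | None = None,
    moa: MoaMap | None = None,
    plan: SplitPlan | None = None,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """k-fold cross-validated train/evaluate; returns fold reports + summary.

    The summary aggregates every metric across folds (median, mean, sd) per
    scope (bulk / drug / drug_averaged / moa). Pass preloaded data/plan to
    share them across ablation cells.
    """
    if dataset is None or table is None:
        dataset, table, moa = load_data(config.data)
    if plan is None:
        plan = make_plan(table, config.split)
    reports: list[MetricsReport] = []
    for fold in range(plan.k):
        train_idx = plan.train_indices(fold)
        test_idx = plan.test_indices(fold)
        model, scaler, history = _fit_fold_model(
            dataset,
            train_idx,
            config.sampler,
            config.loss,
            config.model,
            config.train,
            fold,
        )
        report = evaluate_fold(
            model, scaler, dataset, test_idx, moa, config.min_group_size
        )
        reports.append(report)
        logger.info(
            "fold %d/%d: bulk R2=%.4f drug-avg R2=%.4f (final train loss %.5f)",
            fold + 1,
            plan.k,
            report.bulk.get("r2", float("nan")),
            report.group_averaged.get("r2", float("nan")),
            history[-1]["train_loss"],
        )
    summary = aggregate_folds(reports)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, report in enumerate(reports):
            report.to_json(out / f"fold_{i}.json")
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        write_plan(plan, out / "split_plan.tsv")
    return reports, summary


ABLATION_CELLS = (
    ("sequential", "mse"),
    ("sequential", "moorle"),
    ("mixed", "mse"),
    ("mixed", "moorle"),
)


def run_ablation(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    delta_between: tuple[tuple[str, str], tuple[str, str]] = (
        ("sequential", "mse"),
        ("sequential", "moorle"),
    ),
) -> dict[str, Any]:
    """2 samplers x 2 losses on one shared split plan and shared seeds.

    Returns the per-cell fold reports, a cell x metric median table (the
    ablation-grid view), and per-drug / per-MOA improvement deltas between
    the two requested cells.
    """
    dataset, table, moa = load_data(config.data)
    plan = make_plan(table, config.split)
    cells: dict[tuple[str, str], list[MetricsReport]] = {}
    for strategy, loss_kind in ABLATION_CELLS:
        cell_cfg = ExperimentConfig(
            data=config.data,
            split=config.split,
            sampler=SamplerConfig(
                strategy=strategy,
                batch_size=config.sampler.batch_size,
                mixing_weight=config.sampler.mixing_weight,
                seed=config.sampler.seed,
            ),
            loss=LossConfig(
                loss_kind=loss_kind,
                regularization_weight=config.loss.regularization_weight,
            ),
            model=config.model,
            train=config.train,
            min_group_size=config.min_group_size,
        )
        reports, _ = run_cv_experiment(
            cell_cfg, dataset=dataset, table=table, moa=moa, plan=plan
        )
        cells[(strategy, loss_kind)] = reports

    rows = []
    for (strategy, loss_kind), reports in cells.items():
        agg = aggregate_folds(reports)
        for scope in ("bulk", "drug_averaged"):
            sub = agg[(agg["scope"] == scope) & (agg["group"] == "")]
            row: dict[str, Any] = {
                "sampler": strategy,
                "loss": loss_kind,
                "scope": scope,
            }
            for rec in sub.itertuples():
                row[rec.metric] = rec.median
                row[f"{rec.metric}_sd"] = rec.std
            rows.append(row)
    grid = pd.DataFrame(rows)

    cell_a, cell_b = delta_between
    deltas = _median_deltas(cells[cell_a], cells[cell_b], moa)
    result = {
        "cells": {f"{s}+{l}": r for (s, l), r in cells.items()},
        "grid": grid,
        "deltas": deltas,
        "plan": plan,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out / "ablation_grid.tsv", sep="\t", index=False)
        write_plan(plan, out / "split_plan.tsv")
        (out / "deltas.json").write_text(json.dumps(deltas, indent=2, sort_keys=True))
    return result


def _median_report(reports: list[MetricsReport]) -> MetricsReport:
    """Per-group metrics taken as the across-fold median for each drug/MOA."""

    def med(parts: list[dict[str, dict[str, float]]]) -> dict[str, dict[str, float]]:
        groups: dict[str, dict[str, list[float]]] = {}
        for part in parts:
            for g, metrics in part.items():
                for m, v in metrics.items():
                    groups.setdefault(g, {}).setdefault(m, []).append(v)
        return {
            g: {m: float(np.nanmedian(vs)) for m, vs in metrics.items()}
            for g, metrics in groups.items()
        }

    return MetricsReport(
        bulk={},
        per_group=med([r.per_group for r in reports]),
        moa_averaged=med([r.moa_averaged for r in reports]),
    )


def _median_deltas(
    reports_a: list[MetricsReport],
    reports_b: list[MetricsReport],
    moa: MoaMap | None,
) -> dict[str, Any]:
    med_a, med_b = _median_report(reports_a), _median_report(reports_b)
    common = sorted(set(med_a.per_group) & set(med_b.per_group))
    med_a.per_group = {g: med_a.per_group[g] for g in common}
    med_b.per_group = {g: med_b.per_group[g] for g in common}
    out: dict[str, Any] = {"drug": improvement_deltas(med_a, med_b, scope="drug")}
    if moa is not None:
        common_moa = sorted(set(med_a.moa_averaged) & set(med_b.moa_averaged))
        med_a.moa_averaged = {g: med_a.moa_averaged[g] for g in common_moa}
        med_b.moa_averaged = {g: med_b.moa_averaged[g] for g in common_moa}
        out["moa"] = improvement_deltas(med_a, med_b, scope="moa")
    return out


def sweep_regularization(
    config: ExperimentConfig,
    a_values: tuple[float, ...] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Sweep the regularization weight a; pick the best by validation score.

    For each fold a drug-disjoint (in drug_blind mode) validation holdout
    is carved from the training portion; each candidate a trains on the
    reduced training set and is scored on validation and test. a = 0 runs
    the plain-MSE baseline (the unregularized reference the sweep is
    compared against). Best a maximizes mean validation drug-averaged R^2.
    """
    a_values = tuple(a_values if a_values is not None else config.sweep_grid)
    if not a_values or any(a < 0 for a in a_values):
        raise ValueError("a_values must be non-empty and non-negative")
    dataset, table, moa = load_data(config.data)
    plan = make_plan(table, config.split)

    rows = []
    val_scores: dict[float, list[float]] = {a: [] for a in a_values}
    test_reports: dict[float, list[MetricsReport]] = {a: [] for a in a_values}
    for fold in range(plan.k):
        tr_idx, val_idx = validation_holdout(
            plan,
            fold,
            config.split.validation_fraction,
            seed=config.split.seed * 1009 + fold,
            table=table,
        )
        test_idx = plan.test_indices(fold)
        for a in a_values:
            loss = (
                LossConfig(loss_kind="mse")
                if a == 0
                else LossConfig(loss_kind="moorle", regularization_weight=a)
            )
            model, scaler, _ = _fit_fold_model(
                dataset,
                tr_idx,
                config.sampler,
                loss,
                config.model,
                config.train,
                fold,
                val_idx=val_idx,
            )
            val_report = evaluate_fold(
                model, scaler, dataset, val_idx, moa, config.min_group_size
            )
            test_report = evaluate_fold(
                model, scaler, dataset, test_idx, moa, config.min_group_size
            )
            val_scores[a].append(val_report.group_averaged.get("r2", float("nan")))
            test_reports[a].append(test_report)

    for a in a_values:
        agg = aggregate_folds(test_reports[a])
        for scope in ("bulk", "drug_averaged"):
            sub = agg[(agg["scope"] == scope) & (agg["group"] == "")]
            row: dict[str, Any] = {
                "a": a,
                "scope": scope,
                "val_drug_avg_r2": float(np.nanmean(val_scores[a])),
            }
            for rec in sub.itertuples():
                row[rec.metric] = rec.mean
                row[f"{rec.metric}_sd"] = rec.std
                row[f"{rec.metric}_median"] = rec.median
            rows.append(row)
    summary = pd.DataFrame(rows)
    mean_val = {a: float(np.nanmean(val_scores[a])) for a in a_values}
    best_a = max(a_values, key=lambda a: (mean_val[a], -a))
    result = {
        "summary": summary,
        "best_a": best_a,
        "validation_scores": mean_val,
        "test_reports": test_reports,
        "plan": plan,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "sweep_summary.tsv", sep="\t", index=False)
        (out / "best_a.json").write_text(
            json.dumps({"best_a": best_a, "validation_scores": mean_val}, indent=2)
        )
        write_plan(plan, out / "split_plan.tsv")
    return result
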