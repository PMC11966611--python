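"""Bulk, per-drug, drug-averaged and MOA-averaged performance metrics.

A bulk metric over all test pairs is dominated by heavily sampled drugs.
The group-wise view computes each metric *within* each drug's records and
then averages with equal weight per drug, which is insensitive to per-drug
record counts; MOA-averaging aggregates further over mechanism-of-action
classes. R-squared uses the mean of the evaluated subset as its baseline
(the per-drug mean for drug-wise scores, the test-set mean for bulk), so a
drug-wise R-squared measures goodness of fit for that drug specifically
and is unbounded below.

Drugs with fewer than ``min_group_size`` records or zero target variance
(where R-squared is undefined) are excluded from the averages and listed
with reasons rather than silently dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .data_io import MoaMap

METRIC_NAMES = ("r2", "mse", "mae", "pearson", "spearman")


@dataclass
class MetricsReport:
    bulk: dict[str, float]
    per_group: dict[str, dict[str, float]] = field(default_factory=dict)
    group_averaged: dict[str, float] = field(default_factory=dict)
    moa_averaged: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded_groups: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "bulk": self.bulk,
            "per_group": self.per_group,
            "group_averaged": self.group_averaged,
            "moa_averaged": self.moa_averaged,
            "excluded_groups": [list(e) for e in self.excluded_groups],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tidy(self, fold: int | str = 0) -> pd.DataFrame:
        """Long-format (fold, scope, group, metric, value) frame."""
        rows = [
            (fold, "bulk", "", m, v) for m, v in self.bulk.items()
        ]
        rows += [
            (fold, "drug", g, m, v)
            for g, metrics in self.per_group.items()
            for m, v in metrics.items()
        ]
        rows += [
            (fold, "drug_averaged", "", m, v) for m, v in self.group_averaged.items()
        ]
        rows += [
            (fold, "moa", g, m, v)
            for g, metrics in self.moa_averaged.items()
            for m, v in metrics.items()
        ]
        return pd.DataFrame(rows, columns=["fold", "scope", "group", "metric", "value"])


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS over the evaluated set.

    The baseline mean is taken over the evaluated records themselves.
    Unbounded below; undefined (ValueError) when y has zero variance.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("r_squared needs two equal-length vectors of size >= 2")
    if np.ptp(y) == 0:
        raise ValueError("r_squared undefined for zero-variance targets")
    return float(r2_score(y, y_hat))


def bulk_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """All five standard metrics; correlations are NaN for constant inputs."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("bulk_metrics needs two equal-length vectors of size >= 2")
    out = {
        "mse": float(mean_squared_error(y, y_hat)),
        "mae": float(mean_absolute_error(y, y_hat)),
    }
    out["r2"] = r_squared(y, y_hat) if np.ptp(y) > 0 else float("nan")
    if np.ptp(y) > 0 and np.ptp(y_hat) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["pearson"] = float(stats.pearsonr(y, y_hat).statistic)
            out["spearman"] = float(stats.spearmanr(y, y_hat).statistic)
    else:
        out["pearson"] = float("nan")
        out["spearman"] = float("nan")
    return out


def groupwise_metrics(
    y: np.ndarray,
    y_hat: np.ndarray,
    groups: np.ndarray,
    min_group_size: int = 2,
) -> MetricsReport:
    """Per-drug metrics plus equal-weight drug averages (and the bulk view).

    Exclusion rules: groups smaller than ``min_group_size`` and groups with
    zero target variance are left out of per-group metrics and averages,
    recorded in ``excluded_groups`` with a reason.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    groups = np.asarray(groups)
    if not len(y) == len(y_hat) == len(groups):
        raise ValueError("y, y_hat and groups must be aligned")
    per_group: dict[str, dict[str, float]] = {}
    excluded: list[tuple[str, str]] = []
    for g in np.unique(groups):
        mask = groups == g
        n_g = int(mask.sum())
        if n_g < min_group_size:
            excluded.append((str(g), f"fewer than {min_group_size} records ({n_g})"))
            continue
        if np.ptp(y[mask]) == 0:
            excluded.append((str(g), "zero target variance"))
            continue
        per_group[str(g)] = bulk_metrics(y[mask], y_hat[mask])
    group_averaged = {
        m: (
            float(np.nanmean([v[m] for v in per_group.values()]))
            if per_group
            else float("nan")
        )
        for m in METRIC_NAMES
    }
    return MetricsReport(
        bulk=bulk_metrics(y, y_hat) if len(y) >= 2 else {},
        per_group=per_group,
        group_averaged=group_averaged,
        excluded_groups=excluded,
    )


def aggregate_by_moa(
    per_group: dict[str, dict[str, float]], moa: MoaMap
) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Unweighted mean of member drugs' metrics per MOA label.

    Drugs absent from the map are skipped and returned in the second slot.
    """
    members: dict[str, list[dict[str, float]]] = {}
    skipped: list[str] = []
    for drug, metrics in per_group.items():
        if drug not in moa:
            skipped.append(drug)
            continue
        members.setdefault(moa[drug], []).append(metrics)
    moa_averaged = {
        label: {
            m: float(np.nanmean([metrics[m] for metrics in group]))
            for m in METRIC_NAMES
        }
        for label, group in sorted(members.items())
    }
    return moa_averaged, sorted(skipped)


def attach_moa(report: MetricsReport, moa: MoaMap) -> MetricsReport:
    report.moa_averaged, skipped = aggregate_by_moa(report.per_group, moa)
    report.excluded_groups.extend((d, "missing from MOA map") for d in skipped)
    return report


def improvement_deltas(
    report_a: MetricsReport, report_b: MetricsReport, scope: str = "drug"
) -> dict[str, dict[str, float]]:
    """Per-drug (or per-MOA) metric deltas, metric(b) - metric(a).

    Positive delta means ``report_b`` improves on ``report_a`` for metrics
    where larger is better (R^2, correlations); for MSE/MAE smaller is
    better, the delta is still b - a.
    """
    part_a = report_a.per_group if scope == "drug" else report_a.moa_averaged
    part_b = report_b.per_group if scope == "drug" else report_b.moa_averaged
    if set(part_a) != set(part_b):
        only_a = sorted(set(part_a) - set(part_b))
        only_b = sorted(set(part_b) - set(part_a))
        raise ValueError(
            f"mismatched group sets — only in first: {only_a}, only in second: {only_b}"
        )
    return {
        g: {m: part_b[g][m] - part_a[g][m] for m in part_a[g]}
        for g in sorted(part_a)
    }


def top_improvements(
    deltas: dict[str, dict[str, float]], metric: str = "r2", k: int = 10
) -> list[tuple[str, float]]:
    """The k largest deltas for one metric, descending (Top-k gains view)."""
    ranked = sorted(
        ((g, d[metric]) for g, d in deltas.items() if np.isfinite(d.get(metric, np.nan))),
        key=lambda item: -item[1],
    )
    return ranked[:k]


def aggregate_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Median / mean / sd of each metric across CV folds, per scope.

    The median is the headline aggregate (robust to the large fold-to-fold
    variation drug-wise R^2 shows); mean and sd are reported alongside.
    """
    tidy = pd.concat(
        [r.to_tidy(fold=i) for i, r in enumerate(reports)], ignore_index=True
    )
    agg = (
        tidy.groupby(["scope", "group", "metric"])["value"]
        .agg(["median", "mean", "std"])
        .reset_index()
    )
    return agg
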