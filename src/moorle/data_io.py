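"""Core dataset containers and delimited-text I/O.

Drug response prediction (DRP) datasets are *pair-input*: every record
couples a biological sample (cell line) with a compound and carries a
continuous response such as the area under the dose-response curve (AUC).
This module defines the in-memory containers for the response table, the
per-entity feature matrices, and the drug -> mechanism-of-action (MOA)
mapping, plus readers/writers for the tab-separated formats the toolkit
exchanges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {"sample": "sample_id", "drug": "drug_id", "response": "auc"}


class DataFormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class ResponsePair:
    """A single (cell line, drug) experiment with its continuous response."""

    sample_id: str
    drug_id: str
    response: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.response):
            raise ValueError(
                f"non-finite response for pair ({self.sample_id}, {self.drug_id})"
            )


@dataclass
class DrugResponseTable:
    """Ordered collection of unique (sample, drug) response records."""

    records: list[ResponsePair]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.drug_id)
            if key in seen:
                raise DataFormatError(f"duplicate (sample, drug) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> set[str]:
        return {r.sample_id for r in self.records}

    @property
    def drug_ids(self) -> set[str]:
        return {r.drug_id for r in self.records}

    def drug_counts(self) -> dict[str, int]:
        """Number of records per drug (the imbalance profile of the table)."""
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.drug_id] = counts.get(r.drug_id, 0) + 1
        return counts

    def responses(self) -> np.ndarray:
        return np.array([r.response for r in self.records], dtype=float)

    def group_labels(self) -> np.ndarray:
        """Drug id per record, aligned with ``records`` order."""
        return np.array([r.drug_id for r in self.records], dtype=object)

    def to_frame(self, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
        cols = dict(DEFAULT_COLUMNS, **(columns or {}))
        return pd.DataFrame(
            {
                cols["sample"]: [r.sample_id for r in self.records],
                cols["drug"]: [r.drug_id for r in self.records],
                cols["response"]: [r.response for r in self.records],
            }
        )


@dataclass
class FeatureMatrix:
    """Dense entity x feature matrix with ordered, unique row identifiers."""

    entity_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            dupes = sorted(
                {e for e in self.entity_ids if self.entity_ids.count(e) > 1}
            )
            raise DataFormatError(f"duplicate entity ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                f"non-finite value at entity {self.entity_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self._index[entity_id]]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index


@dataclass
class MoaMap:
    """Drug id -> mechanism-of-action label (each drug has exactly one MOA)."""

    mapping: dict[str, str]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.mapping

    def __getitem__(self, drug_id: str) -> str:
        return self.mapping[drug_id]

    def labels(self) -> set[str]:
        return set(self.mapping.values())


@dataclass
class JoinedDataset:
    """Pair records joined with concatenated sample+drug feature vectors.

    ``features`` is (n_pairs, sample_dim + drug_dim); ``groups`` keeps the
    drug id per pair so batch losses can be decomposed per drug.
    """

    features: np.ndarray
    responses: np.ndarray
    groups: np.ndarray
    sample_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    feature_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.responses)

    @property
    def input_dim(self) -> int:
        return 0 if self.features.size == 0 else self.features.shape[1]


def _sep(delimiter: str) -> str:
    if delimiter not in ("\t", ","):
        raise ValueError("delimiter must be tab or comma")
    return delimiter


def read_response_table(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> DrugResponseTable:
    """Read a pair-input response table from a delimited text file.

    ``column_spec`` maps the roles ``sample``, ``drug``, ``response`` onto
    column names; defaults to ``sample_id``/``drug_id``/``auc``. Row order
    is preserved. Duplicate (sample, drug) pairs and non-numeric responses
    are rejected with messages naming the offending row.
    """
    cols = dict(DEFAULT_COLUMNS, **(column_spec or {}))
    df = pd.read_csv(path, sep=_sep(delimiter), dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, cols["response"])
        try:
            resp = float(raw)
        except (TypeError, ValueError) as exc:
            raise DataFormatError(
                f"{path}: non-numeric response {raw!r} in data row {i}"
            ) from exc
        records.append(
            ResponsePair(getattr(row, cols["sample"]), getattr(row, cols["drug"]), resp)
        )
    table = DrugResponseTable(records)
    out_of_range = [r for r in table.records if not 0.0 <= r.response <= 1.0]
    if out_of_range:
        logger.warning(
            "%s: %d responses outside [0, 1]; AUC-like values are expected but "
            "no clipping is applied",
            path,
            len(out_of_range),
        )
    return table


def write_response_table(
    table: DrugResponseTable,
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> None:
    table.to_frame(column_spec).to_csv(path, sep=_sep(delimiter), index=False)


def read_feature_matrix(
    path: str | Path,
    rows_are_entities: bool = True,
    delimiter: str = "\t",
) -> FeatureMatrix:
    """Read an entity x feature matrix (first column = entity id, header = names).

    With ``rows_are_entities=False`` the file is transposed after reading, so a
    features-as-rows file yields the same matrix as its transpose read plainly.
    """
    df = pd.read_csv(path, sep=_sep(delimiter), index_col=0)
    if not rows_are_entities:
        df = df.T
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise DataFormatError(f"{path}: duplicate entity ids: {dupes}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise DataFormatError(
            f"{path}: non-finite value at entity {df.index[i]!r}, "
            f"feature {df.columns[j]!r}"
        )
    return FeatureMatrix(
        entity_ids=[str(e) for e in df.index],
        feature_names=[str(c) for c in df.columns],
        values=values,
    )


def write_feature_matrix(
    matrix: FeatureMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.entity_ids, columns=matrix.feature_names
    )
    df.index.name = "id"
    df.to_csv(path, sep=_sep(delimiter))


def read_moa_map(path: str | Path, delimiter: str = "\t") -> MoaMap:
    df = pd.read_csv(path, sep=_sep(delimiter), dtype=str)
    for col in ("drug_id", "moa"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    if df["drug_id"].duplicated().any():
        dupes = sorted(set(df["drug_id"][df["drug_id"].duplicated()]))
        raise DataFormatError(f"{path}: drugs mapped to multiple MOAs: {dupes}")
    return MoaMap(dict(zip(df["drug_id"], df["moa"])))


def write_moa_map(moa: MoaMap, path: str | Path, delimiter: str = "\t") -> None:
    pd.DataFrame(
        {"drug_id": list(moa.mapping), "moa": list(moa.mapping.values())}
    ).to_csv(path, sep=_sep(delimiter), index=False)


def assemble_dataset(
    table: DrugResponseTable,
    sample_features: FeatureMatrix,
    drug_features: FeatureMatrix,
) -> JoinedDataset:
    """Join each response pair with its concatenated feature vector.

    Output record order follows ``table.records``. Every sample and drug id
    in the table must be present in the respective matrix.
    """
    missing_samples = sorted(table.sample_ids - set(sample_features.entity_ids))
    missing_drugs = sorted(table.drug_ids - set(drug_features.entity_ids))
    if missing_samples or missing_drugs:
        raise DataFormatError(
            f"unmatched ids — samples: {missing_samples}, drugs: {missing_drugs}"
        )
    n = len(table)
    dim = sample_features.n_features + drug_features.n_features
    features = np.empty((n, dim), dtype=float)
    for i, rec in enumerate(table.records):
        features[i, : sample_features.n_features] = sample_features.row(rec.sample_id)
        features[i, sample_features.n_features :] = drug_features.row(rec.drug_id)
    return JoinedDataset(
        features=features,
        responses=table.responses(),
        groups=table.group_labels(),
        sample_ids=np.array([r.sample_id for r in table.records], dtype=object),
        feature_names=[f"sample:{f}" for f in sample_features.feature_names]
        + [f"drug:{f}" for f in drug_features.feature_names],
    )
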