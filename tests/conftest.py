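from __future__ import annotations

import numpy as np
import pytest

from moorle.data_io import DrugResponseTable, FeatureMatrix, ResponsePair
from moorle.loss import GroupedBatch
from moorle.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_grouped_batch(
    rng: np.random.Generator, max_pairs: int = 50, max_groups: int = 6
) -> GroupedBatch:
    """A random prediction/target batch with 1..max_groups drugs."""
    k = int(rng.integers(1, max_groups + 1))
    n = int(rng.integers(k, max_pairs + 1))
    labels = np.array([f"D{i}" for i in range(k)])
    # every drug appears at least once
    groups = np.concatenate([labels, rng.choice(labels, size=n - k)])
    rng.shuffle(groups)
    return GroupedBatch(
        targets=rng.normal(0.5, 0.3, size=n),
        group_labels=groups,
        predictions=rng.normal(0.5, 0.5, size=n),
    )


@pytest.fixture
def small_table() -> DrugResponseTable:
    records = [
        ResponsePair("c1", "A", 0.2),
        ResponsePair("c2", "A", 0.4),
        ResponsePair("c3", "A", 0.6),
        ResponsePair("c1", "B", 0.8),
        ResponsePair("c2", "B", 0.5),
        ResponsePair("c3", "C", 0.1),
        ResponsePair("c4", "C", 0.3),
        ResponsePair("c4", "A", 0.9),
    ]
    return DrugResponseTable(records)


@pytest.fixture
def tiny_features() -> tuple[FeatureMatrix, FeatureMatrix]:
    samples = FeatureMatrix(
        entity_ids=["c1", "c2", "c3", "c4"],
        feature_names=["g1", "g2", "g3", "g4"],
        values=np.arange(16, dtype=float).reshape(4, 4),
    )
    drugs = FeatureMatrix(
        entity_ids=["A", "B", "C"],
        feature_names=["d1", "d2"],
        values=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )
    return samples, drugs


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact ctrp-like dataset reused across integration tests."""
    spec = SyntheticSpec(
        n_samples=60,
        n_drugs=12,
        sample_feature_dim=8,
        drug_feature_dim=5,
        count_profile="ctrp_like",
        max_count=40,
        noise_sd=0.05,
        n_moa=4,
        seed=11,
    )
    return spec, generate_dataset(spec)
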