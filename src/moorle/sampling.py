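"""Epoch sampling strategies for minibatch training on imbalanced pair data.

Two strategies are provided:

* ``sequential`` — shuffled sequential sampling: each record drawn exactly
  once per epoch in seeded random order (the SGD default). Under a
  long-tailed per-drug count profile, rare drugs contribute few gradient
  steps per epoch.
* ``mixed`` — weighted with-replacement sampling interpolating between
  uniform record sampling (lambda = 0) and fully drug-balanced sampling
  (lambda = 1, every drug equally likely per draw). Per-record weight for
  a record of drug d:  w(d) = (1 - lambda)/N + lambda/(|D| * count(d)).

All samplers are deterministic given (seed, config, dataset order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SamplerConfig:
    strategy: str = "sequential"
    batch_size: int = 64
    mixing_weight: float = 0.5  # lambda, mixed strategy only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("sequential", "mixed"):
            raise ValueError(f"unknown sampling strategy {self.strategy!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must lie in [0, 1]")


def _chunk(indices: np.ndarray, batch_size: int) -> list[np.ndarray]:
    return [indices[i : i + batch_size] for i in range(0, len(indices), batch_size)]


def sequential_shuffled(n_records: int, config: SamplerConfig) -> list[np.ndarray]:
    """One epoch of shuffled sequential batches: a seeded permutation, chunked.

    Every index in [0, n) appears exactly once; the last batch may be short.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(config.seed)
    return _chunk(rng.permutation(n_records), config.batch_size)


def mixed_weights(drug_counts: dict, mixing_weight: float) -> dict:
    """Per-record sampling weight for each drug under the lambda-blend.

    ``w(d) = (1-lambda)/N + lambda/(|D| * count(d))``; summed over all
    records the weights total 1 by construction (renormalized to absorb
    rounding). lambda=0 gives uniform record sampling, lambda=1 gives each
    drug equal total mass.
    """
    if not drug_counts:
        raise ValueError("drug_counts must be non-empty")
    if any(c < 1 for c in drug_counts.values()):
        zero = [d for d, c in drug_counts.items() if c < 1]
        raise ValueError(f"drugs with zero records: {zero}")
    if not 0.0 <= mixing_weight <= 1.0:
        raise ValueError("mixing_weight must lie in [0, 1]")
    n_total = sum(drug_counts.values())
    k = len(drug_counts)
    raw = {
        d: (1.0 - mixing_weight) / n_total + mixing_weight / (k * c)
        for d, c in drug_counts.items()
    }
    total = sum(w * drug_counts[d] for d, w in raw.items())
    return {d: w / total for d, w in raw.items()}


def record_weights(group_labels: np.ndarray, mixing_weight: float) -> np.ndarray:
    """Expand per-drug weights to a normalized per-record weight vector."""
    group_labels = np.asarray(group_labels)
    labels, inverse = np.unique(group_labels, return_inverse=True)
    counts = np.bincount(inverse)
    per_drug = mixed_weights(dict(zip(labels, counts.tolist())), mixing_weight)
    w = np.array([per_drug[label] for label in labels])[inverse]
    return w / w.sum()


def sample_epoch(
    n_records: int, weights: np.ndarray, config: SamplerConfig
) -> list[np.ndarray]:
    """One epoch of weighted with-replacement batches.

    Draws ``n_records`` indices according to ``weights`` (epoch length
    matches the dataset so gradient-step counts are comparable with the
    sequential strategy), then chunks consecutively into batches.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    if len(weights) != n_records:
        raise ValueError("one weight per record required")
    rng = np.random.default_rng(config.seed)
    drawn = rng.choice(n_records, size=n_records, replace=True, p=weights)
    return _chunk(drawn, config.batch_size)


def epoch_batches(
    group_labels: np.ndarray, config: SamplerConfig, epoch: int = 0
) -> list[np.ndarray]:
    """Batches for one epoch under the configured strategy.

    The epoch number is folded into the seed so successive epochs differ
    while the whole trajectory stays reproducible.
    """
    n = len(group_labels)
    epoch_cfg = SamplerConfig(
        strategy=config.strategy,
        batch_size=config.batch_size,
        mixing_weight=config.mixing_weight,
        seed=(config.seed * 100003 + epoch) % (2**31 - 1),
    )
    if config.strategy == "sequential":
        return sequential_shuffled(n, epoch_cfg)
    weights = record_weights(group_labels, config.mixing_weight)
    return sample_epoch(n, weights, epoch_cfg)
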