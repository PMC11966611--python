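"""Synthetic pair-input drug-response data with known ground truth.

Emulates the imbalance structure of public cell-line screens so the whole
toolkit is testable without downloads:

* ``ccle_like`` — mild imbalance, few drugs: most drugs screened against
  nearly the full cell-line panel, ~12.5% of drugs below 90% of the
  maximum per-drug experiment count.
* ``ctrp_like`` — strong imbalance, many drugs: ~17% of drugs below 50%
  of the maximum count and ~20% between 50% and 90%, the rest near the
  maximum.

Responses are AUC-like values in [0, 1]: a smooth ground-truth surface
(linear sample term + linear drug term + bilinear interaction, squashed
through a logistic) plus additive Gaussian noise. Drugs are grouped into
MOA clusters sharing a latent feature centre, so mechanism-of-action
aggregation sees real structure and drug-blind generalization is possible
in principle. The generator records all latent parameters so the noiseless
predictor — the performance ceiling of any model — is available as an
oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    DrugResponseTable,
    FeatureMatrix,
    MoaMap,
    ResponsePair,
)

PROFILES = ("uniform", "ccle_like", "ctrp_like")

# Bucket fractions of the per-drug experiment-count histograms being emulated
CCLE_BELOW_90 = 0.125
CTRP_BELOW_50 = 0.172
CTRP_50_TO_90 = 0.196


@dataclass
class SyntheticSpec:
    n_samples: int = 200
    n_drugs: int = 24
    sample_feature_dim: int = 20
    drug_feature_dim: int = 10
    count_profile: str = "ccle_like"
    max_count: int = 150
    noise_sd: float = 0.05
    drug_effect_scale: float = 0.5
    interaction_scale: float = 1.0
    n_moa: int = 6
    seed: int = 0
    explicit_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.explicit_counts is None and self.count_profile not in PROFILES:
            raise ValueError(f"unknown count profile {self.count_profile!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_moa < 1 or self.n_moa > self.n_drugs:
            raise ValueError("n_moa must lie in [1, n_drugs]")


@dataclass
class GroundTruth:
    """Latent parameters plus the noiseless response for every generated pair."""

    sample_weights: np.ndarray
    drug_weights: np.ndarray
    interaction: np.ndarray
    interaction_scale: float
    noise_sd: float
    noiseless: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_weights": self.sample_weights.tolist(),
            "drug_weights": self.drug_weights.tolist(),
            "interaction": self.interaction.tolist(),
            "interaction_scale": self.interaction_scale,
            "noise_sd": self.noise_sd,
            "noiseless": {f"{s}\t{d}": v for (s, d), v in self.noiseless.items()},
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def imbalance_profile(
    n_drugs: int, max_count: int, profile: str, seed: int
) -> np.ndarray:
    """Per-drug experiment counts following a named imbalance profile.

    At least one drug sits exactly at ``max_count``; bucket membership is
    strict (a "below 50%" drug has count < ceil(0.5 * max)). Which drugs
    land in which bucket is a seeded shuffle.
    """
    if n_drugs < 1 or max_count < 1:
        raise ValueError("n_drugs and max_count must be >= 1")
    if profile not in PROFILES:
        raise ValueError(f"unknown count profile {profile!r}")
    if profile == "uniform":
        return np.full(n_drugs, max_count, dtype=int)
    rng = np.random.default_rng(seed)
    lo50 = int(np.ceil(0.5 * max_count))
    lo90 = int(np.ceil(0.9 * max_count))
    floor = max(1, int(np.ceil(0.05 * max_count)))

    def _uniform(n: int, low: int, high: int) -> np.ndarray:
        # inclusive band, degenerate bands collapse to the low edge
        high = max(low, high)
        return rng.integers(low, high + 1, size=n)

    if profile == "ccle_like":
        n_low = round(CCLE_BELOW_90 * n_drugs)
        counts = np.concatenate(
            [
                _uniform(n_low, max(floor, lo50), lo90 - 1),
                _uniform(n_drugs - n_low, lo90, max_count),
            ]
        )
    else:  # ctrp_like
        n_red = round(CTRP_BELOW_50 * n_drugs)
        n_yellow = round(CTRP_50_TO_90 * n_drugs)
        n_blue = n_drugs - n_red - n_yellow
        counts = np.concatenate(
            [
                _uniform(n_red, floor, lo50 - 1),
                _uniform(n_yellow, lo50, lo90 - 1),
                _uniform(n_blue, lo90, max_count),
            ]
        )
    counts = np.clip(counts, 1, max_count).astype(int)
    rng.shuffle(counts)
    counts[int(np.argmax(counts))] = max_count  # anchor the histogram peak
    return counts


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, FeatureMatrix, DrugResponseTable, MoaMap, GroundTruth]:
    """Generate (sample features, drug features, response table, MOA map, truth).

    Response for pair (c, d):
        logistic( <w_c, x_c> + <w_d, x_d> + s_int * x_c' M x_d ) + N(0, noise_sd)
    with all weight entries O(1/sqrt(dim)) so the pre-squash score has
    roughly unit scale. Each drug's record count follows the requested
    profile; cell-line subsets are sampled without replacement, so every
    (sample, drug) pair is unique.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.explicit_counts is not None:
        counts = np.asarray(spec.explicit_counts, dtype=int)
        if len(counts) != spec.n_drugs:
            raise ValueError("explicit_counts length must equal n_drugs")
    else:
        counts = imbalance_profile(
            spec.n_drugs, spec.max_count, spec.count_profile, spec.seed
        )
    if counts.min() < 1:
        raise ValueError("per-drug counts must be >= 1")
    if counts.max() > spec.n_samples:
        raise ValueError(
            f"per-drug count {counts.max()} exceeds n_samples={spec.n_samples}; "
            "pairs must be unique"
        )

    sample_ids = [f"CL{i:04d}" for i in range(spec.n_samples)]
    drug_ids = [f"DRUG{j:03d}" for j in range(spec.n_drugs)]
    X_samples = rng.normal(size=(spec.n_samples, spec.sample_feature_dim))

    # MOA clusters: shared latent centre + drug-specific perturbation
    moa_of = {d: f"MOA{j % spec.n_moa:02d}" for j, d in enumerate(drug_ids)}
    centres = rng.normal(size=(spec.n_moa, spec.drug_feature_dim))
    X_drugs = np.vstack(
        [
            centres[j % spec.n_moa]
            + spec.drug_effect_scale * rng.normal(size=spec.drug_feature_dim)
            for j in range(spec.n_drugs)
        ]
    )

    sf, df = spec.sample_feature_dim, spec.drug_feature_dim
    truth = GroundTruth(
        sample_weights=rng.normal(size=sf) / np.sqrt(sf),
        drug_weights=rng.normal(size=df) / np.sqrt(df),
        interaction=rng.normal(size=(sf, df)) / np.sqrt(sf * df),
        interaction_scale=spec.interaction_scale,
        noise_sd=spec.noise_sd,
    )

    records: list[ResponsePair] = []
    for j, d in enumerate(drug_ids):
        chosen = rng.choice(spec.n_samples, size=int(counts[j]), replace=False)
        xd = X_drugs[j]
        score = (
            X_samples[chosen] @ truth.sample_weights
            + xd @ truth.drug_weights
            + spec.interaction_scale * (X_samples[chosen] @ truth.interaction @ xd)
        )
        clean = _logistic(score)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(chosen))
        for c_idx, mu, y in zip(chosen, clean, noisy):
            s = sample_ids[int(c_idx)]
            truth.noiseless[(s, d)] = float(mu)
            records.append(ResponsePair(s, d, float(y)))

    sample_matrix = FeatureMatrix(
        entity_ids=sample_ids,
        feature_names=[f"g{i}" for i in range(sf)],
        values=X_samples,
    )
    drug_matrix = FeatureMatrix(
        entity_ids=drug_ids,
        feature_names=[f"desc{i}" for i in range(df)],
        values=X_drugs,
    )
    return (
        sample_matrix,
        drug_matrix,
        DrugResponseTable(records),
        MoaMap(moa_of),
        truth,
    )


def oracle_metrics(
    table: DrugResponseTable, ground_truth: GroundTruth
) -> dict[str, float]:
    """Per-drug R-squared ceiling: the noiseless predictor scored on noisy data.

    No model can systematically beat this; with noise_sd = 0 every ceiling
    is 1, and as noise grows the ceilings fall toward 0 (roughly
    var(signal) / (var(signal) + noise_sd^2) per drug).
    """
    missing = [
        (r.sample_id, r.drug_id)
        for r in table.records
        if (r.sample_id, r.drug_id) not in ground_truth.noiseless
    ]
    if missing:
        raise ValueError(
            f"table contains pairs unknown to this ground truth, e.g. {missing[:3]}"
        )
    ceilings: dict[str, float] = {}
    for d in sorted(table.drug_ids):
        recs = [r for r in table.records if r.drug_id == d]
        y = np.array([r.response for r in recs])
        mu = np.array([ground_truth.noiseless[(r.sample_id, r.drug_id)] for r in recs])
        if len(y) < 2 or np.ptp(y) == 0:
            ceilings[d] = float("nan")
            continue
        ss_res = float(((y - mu) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ceilings[d] = 1.0 - ss_res / ss_tot
    return ceilings
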