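"""MOORLE loss: entropy-regularized multi-objective training objective.

A pair-input drug response dataset decomposes into per-drug subproblems.
Plain MSE over all pairs lets over-represented drugs dominate training;
the MOORLE objective (Multi-Objective Optimization Regularized by Loss
Entropy) instead averages per-drug MSEs and penalizes *unevenness* of the
per-drug loss profile:

    L = (1/|D|) * sum_i MSE_{d_i}  +  a * (ln|D| - H(P))

where P = softmax(MSE_{d_1}, ..., MSE_{d_|D|}) and H is Shannon entropy in
nats. H(P) is maximal (= ln|D|) exactly when all per-drug MSEs are equal,
so the regularizer is non-negative and vanishes at a balanced loss profile.
``a >= 0`` trades integral accuracy against balance.

The loss is differentiable with respect to the predictions; gradients flow
through the softmax and entropy terms (P is *not* treated as a constant).
Analytic gradients are provided so the objective can drive any gradient
trainer; see :func:`moorle_gradient`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DISTRIBUTION_TOL = 1e-9


@dataclass
class GroupedBatch:
    """A minibatch carrying targets and per-pair drug labels.

    ``features`` may be omitted when the batch is used purely for loss
    evaluation on precomputed predictions.
    """

    targets: np.ndarray
    group_labels: np.ndarray
    features: np.ndarray | None = None
    predictions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if self.targets.ndim != 1:
            raise ValueError("targets must be a 1-D vector")
        if len(self.group_labels) != len(self.targets):
            raise ValueError("group_labels and targets must have equal length")
        if self.predictions is not None:
            self.predictions = np.asarray(self.predictions, dtype=float)
            if len(self.predictions) != len(self.targets):
                raise ValueError("predictions and targets must have equal length")

    def __len__(self) -> int:
        return len(self.targets)

    def with_predictions(self, predictions: np.ndarray) -> "GroupedBatch":
        return GroupedBatch(
            targets=self.targets,
            group_labels=self.group_labels,
            features=self.features,
            predictions=np.asarray(predictions, dtype=float),
        )


@dataclass
class LossConfig:
    """Loss selection: plain ``mse`` or ``moorle`` with regularization weight a."""

    loss_kind: str = "moorle"
    regularization_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.loss_kind not in ("mse", "moorle"):
            raise ValueError(f"unknown loss_kind {self.loss_kind!r}")
        a = self.regularization_weight
        if not np.isfinite(a) or a < 0:
            raise ValueError("regularization_weight must be finite and >= 0")


@dataclass
class PerGroupLoss:
    """Full decomposition of a MOORLE evaluation on one batch."""

    group_mse: dict
    distribution: dict
    entropy: float
    n_groups: int
    total: float
    mean_group_mse: float = field(default=float("nan"))
    regularizer: float = field(default=float("nan"))


def mse_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error (1/n) * sum (f(x_i) - y_i)^2."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.size == 0 or targets.size == 0:
        raise ValueError("mse_loss requires non-empty vectors")
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal length")
    return float(np.mean((predictions - targets) ** 2))


def mse_gradient(predictions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d MSE / d predictions = 2 (yhat - y) / n."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    return 2.0 * (predictions - targets) / predictions.size


def _group_index(batch: GroupedBatch) -> tuple[np.ndarray, np.ndarray]:
    """Distinct group labels and the per-pair index into them."""
    labels, inverse = np.unique(batch.group_labels, return_inverse=True)
    return labels, inverse


def per_group_mse(batch: GroupedBatch) -> dict:
    """MSE restricted to each drug's pairs; keys are the batch's drug ids."""
    if batch.predictions is None:
        raise ValueError("batch has no predictions attached")
    if len(batch) == 0:
        raise ValueError("empty batch")
    labels, inverse = _group_index(batch)
    sq = (batch.predictions - batch.targets) ** 2
    sums = np.bincount(inverse, weights=sq, minlength=len(labels))
    counts = np.bincount(inverse, minlength=len(labels))
    return {
        (label.item() if hasattr(label, "item") else label): float(s / c)
        for label, s, c in zip(labels, sums, counts)
    }


def normalize_losses(group_mse: dict) -> dict:
    """Softmax of per-drug MSEs: p_i = exp(MSE_i) / sum_j exp(MSE_j).

    Shifted by the max before exponentiation — mathematically identical,
    overflow-safe for arbitrarily large losses.
    """
    if not group_mse:
        raise ValueError("normalize_losses requires a non-empty map")
    values = np.array(list(group_mse.values()), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("per-group losses must be finite")
    p = _softmax(values)
    return dict(zip(group_mse.keys(), p.tolist()))


def _softmax(values: np.ndarray) -> np.ndarray:
    shifted = values - values.max()
    e = np.exp(shifted)
    return e / e.sum()


def entropy(distribution) -> float:
    """Shannon entropy H(P) = -sum p ln p in nats, with 0 ln 0 = 0."""
    if isinstance(distribution, dict):
        p = np.array(list(distribution.values()), dtype=float)
    else:
        p = np.asarray(distribution, dtype=float)
    if p.size == 0:
        raise ValueError("entropy of an empty distribution is undefined")
    if np.any(p < -DISTRIBUTION_TOL):
        raise ValueError("distribution has negative entries")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"distribution sums to {p.sum()}, not 1")
    p = np.clip(p, 0.0, None)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def moorle_loss(batch: GroupedBatch, config: LossConfig | None = None) -> PerGroupLoss:
    """Evaluate the MOORLE objective on a batch; returns the full decomposition.

    ``total = mean(per-drug MSE) + a * (ln|D| - H(P))`` with D the set of
    drugs present in the batch. A single-drug batch has a regularizer of
    exactly zero, so MOORLE degenerates to plain MSE there.
    """
    config = config or LossConfig()
    if len(batch) == 0:
        raise ValueError("empty batch")
    group_mse = per_group_mse(batch)
    mse_values = np.array(list(group_mse.values()), dtype=float)
    k = len(group_mse)
    if k == 1:
        p = np.array([1.0])
        h = 0.0
        reg = 0.0
    else:
        p = _softmax(mse_values)
        h = entropy(p)
        reg = max(np.log(k) - h, 0.0)  # clamp tiny negative rounding
    mean_mse = float(mse_values.mean())
    a = config.regularization_weight if config.loss_kind == "moorle" else 0.0
    return PerGroupLoss(
        group_mse=group_mse,
        distribution=dict(zip(group_mse.keys(), p.tolist())),
        entropy=float(h),
        n_groups=k,
        total=mean_mse + a * reg,
        mean_group_mse=mean_mse,
        regularizer=float(reg),
    )


def moorle_gradient(batch: GroupedBatch, config: LossConfig | None = None) -> np.ndarray:
    """Analytic gradient of the MOORLE total w.r.t. the predictions.

    With m_i the per-drug MSEs, P = softmax(m) and H = H(P):

        dL/dm_i = 1/|D| + a * p_i * (ln p_i + H)

    (the second term is the full derivative of -H(softmax(m)), so gradients
    flow through the distribution), and for pair k in drug i with n_i pairs,
    dm_i/dyhat_k = 2 (yhat_k - y_k) / n_i.
    """
    config = config or LossConfig()
    if batch.predictions is None:
        raise ValueError("batch has no predictions attached")
    labels, inverse = _group_index(batch)
    k = len(labels)
    resid = batch.predictions - batch.targets
    sq = resid**2
    counts = np.bincount(inverse, minlength=k).astype(float)
    m = np.bincount(inverse, weights=sq, minlength=k) / counts
    dL_dm = np.full(k, 1.0 / k)
    a = config.regularization_weight if config.loss_kind == "moorle" else 0.0
    if a > 0 and k > 1:
        p = _softmax(m)
        h = -(p * np.log(p)).sum()
        dL_dm += a * p * (np.log(p) + h)
    return dL_dm[inverse] * 2.0 * resid / counts[inverse]


def batch_loss_and_gradient(
    batch: GroupedBatch, config: LossConfig
) -> tuple[float, np.ndarray]:
    """Dispatch on ``config.loss_kind``: (loss value, d loss / d predictions)."""
    if batch.predictions is None:
        raise ValueError("batch has no predictions attached")
    single_group = len(np.unique(batch.group_labels)) == 1
    if config.loss_kind == "mse" or single_group:
        # |D| = 1 degenerates MOORLE to plain MSE exactly (regularizer == 0,
        # mean of one per-drug MSE == batch MSE); share the code path so the
        # trajectories are bit-identical.
        return (
            mse_loss(batch.predictions, batch.targets),
            mse_gradient(batch.predictions, batch.targets),
        )
    result = moorle_loss(batch, config)
    return result.total, moorle_gradient(batch, config)
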