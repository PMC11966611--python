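"""Reference fully connected regressor and the minibatch training loop.

The network is a small FCNN (dense -> ReLU -> dropout stacks, linear
output) written directly in numpy with hand-derived backpropagation, so
any differentiable batch objective — plain MSE or the MOORLE loss — can
drive it: the trainer asks the loss module for d(loss)/d(predictions) and
backpropagates that vector through the network. Optimization is Adam.

Everything is deterministic given the (model seed, sampler seed) pair:
weight init, dropout masks, and batch order all derive from seeded
generators, so two runs with identical configs produce identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loss import GroupedBatch, LossConfig, batch_loss_and_gradient, mse_loss
from .sampling import SamplerConfig, epoch_batches

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass
class ModelConfig:
    input_dim: int
    hidden_layer_sizes: tuple[int, ...] = (64, 32)
    activation: str = "relu"
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


class Standardizer:
    """Per-feature z-scoring, fit on the training portion only (no leakage)."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant features pass through centred
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


class FCNNRegressor:
    """Feed-forward regressor: feature vector -> scalar prediction."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_layer_sizes, 1]
        # He initialization, suited to ReLU stacks
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._act, self._act_grad = _ACTIVATIONS[config.activation]
        self._cache: dict | None = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Predictions for a (n, input_dim) matrix; caches for backward if training."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] and X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim} features, got {X.shape[1]}"
            )
        a = X
        pre, post, masks = [], [a], []
        p_drop = self.config.dropout_rate
        for layer in range(self.n_layers):
            z = a @ self.weights[layer] + self.biases[layer]
            pre.append(z)
            if layer < self.n_layers - 1:
                a = self._act(z)
                if training and p_drop > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng for dropout")
                    mask = (rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z  # linear output head
            post.append(a)
        if training:
            self._cache = {"pre": pre, "post": post, "masks": masks}
        return a[:, 0]

    def backward(self, grad_predictions: np.ndarray) -> tuple[list, list]:
        """Backpropagate d(loss)/d(predictions) through the cached forward pass."""
        if self._cache is None:
            raise RuntimeError("backward called without a cached training forward pass")
        pre, post, masks = (
            self._cache["pre"],
            self._cache["post"],
            self._cache["masks"],
        )
        delta = np.asarray(grad_predictions, dtype=float)[:, None]
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        for layer in range(self.n_layers - 1, -1, -1):
            grads_w[layer] = post[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
                if masks[layer - 1] is not None:
                    delta = delta * masks[layer - 1]
                delta = delta * self._act_grad(pre[layer - 1])
        return grads_w, grads_b

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[0] == 0:
            return np.empty(0)
        return self.forward(X, training=False)


def build_model(config: ModelConfig) -> FCNNRegressor:
    return FCNNRegressor(config)


class Adam:
    """Adam with the standard moment defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class TrainingDiverged(RuntimeError):
    """Raised when the loss goes non-finite; names the epoch and batch."""


@dataclass
class TrainResult:
    model: FCNNRegressor
    history: list[dict] = field(default_factory=list)


def train_model(
    model: FCNNRegressor,
    features: np.ndarray,
    targets: np.ndarray,
    groups: np.ndarray,
    train_indices: np.ndarray,
    sampler: SamplerConfig,
    loss: LossConfig,
    train_cfg: TrainConfig,
    val_indices: np.ndarray | None = None,
) -> TrainResult:
    """Minibatch-train ``model`` in place on the given training records.

    Each epoch draws batches from the configured sampler, evaluates the
    configured loss on each batch's predictions grouped by drug, and takes
    an Adam step on the backpropagated gradient. History carries one entry
    per epoch (mean batch loss, train MSE, optional validation MSE).

    With ``early_stop_patience`` set and validation indices supplied,
    training stops after that many epochs without validation improvement
    and the best-epoch weights are restored.
    """
    train_indices = np.asarray(train_indices, dtype=int)
    if len(train_indices) == 0:
        raise ValueError("empty training set")
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    groups = np.asarray(groups)
    train_groups = groups[train_indices]

    params = model.weights + model.biases
    opt = Adam(params, train_cfg.learning_rate)
    dropout_rng = np.random.default_rng(train_cfg.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state: tuple[list, list] | None = None
    stale = 0

    for epoch in range(train_cfg.epochs):
        batches = epoch_batches(train_groups, sampler, epoch=epoch)
        epoch_losses = []
        for b, batch_local in enumerate(batches):
            idx = train_indices[batch_local]
            preds = model.forward(X[idx], training=True, rng=dropout_rng)
            gb = GroupedBatch(
                targets=y[idx], group_labels=groups[idx], predictions=preds
            )
            value, grad_pred = batch_loss_and_gradient(gb, loss)
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss {value} at epoch {epoch}, batch {b}"
                )
            grads_w, grads_b = model.backward(grad_pred)
            opt.step(params, grads_w + grads_b)
            epoch_losses.append(value)
        entry = {
            "epoch": epoch,
            "n_batches": len(batches),
            "train_loss": float(np.mean(epoch_losses)),
            "train_mse": mse_loss(model.predict(X[train_indices]), y[train_indices]),
        }
        if val_indices is not None and len(val_indices) > 0:
            entry["val_mse"] = mse_loss(model.predict(X[val_indices]), y[val_indices])
        history.append(entry)
        if train_cfg.early_stop_patience is not None and "val_mse" in entry:
            if entry["val_mse"] < best_val - 1e-12:
                best_val = entry["val_mse"]
                best_state = (
                    [w.copy() for w in model.weights],
                    [b.copy() for b in model.biases],
                )
                stale = 0
            else:
                stale += 1
                if stale >= train_cfg.early_stop_patience:
                    break
    if best_state is not None:
        model.weights[:] = best_state[0]
        model.biases[:] = best_state[1]
    return TrainResult(model=model, history=history)


def predict(model: FCNNRegressor, features: np.ndarray) -> np.ndarray:
    return model.predict(features)
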