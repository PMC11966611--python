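"""FCNN trainer: gradient correctness, learnability, determinism contracts."""

from __future__ import annotations

import numpy as np
import pytest

from moorle.loss import GroupedBatch, LossConfig, batch_loss_and_gradient
from moorle.sampling import SamplerConfig
from moorle.training import (
    FCNNRegressor,
    ModelConfig,
    Standardizer,
    TrainConfig,
    build_model,
    predict,
    train_model,
)


def linear_dataset(n=120, dim=6, noise=0.0, seed=0, n_drugs=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    w = rng.normal(size=dim)
    y = X @ w * 0.2 + 0.5 + rng.normal(0, noise, size=n)
    groups = np.array([f"D{i % n_drugs}" for i in range(n)])
    return X, y, groups


class TestModelBasics:
    def test_forward_shape_and_finiteness(self):
        model = build_model(ModelConfig(input_dim=6, hidden_layer_sizes=(8,), seed=0))
        out = model.predict(np.zeros((3, 6)))
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))

    def test_seed_determinism_of_init(self):
        cfg = ModelConfig(input_dim=4, hidden_layer_sizes=(5,), seed=42)
        X = np.random.default_rng(0).normal(size=(7, 4))
        np.testing.assert_array_equal(
            build_model(cfg).predict(X), build_model(cfg).predict(X)
        )

    def test_wrong_input_width_error(self):
        model = build_model(ModelConfig(input_dim=6, seed=0))
        with pytest.raises(ValueError, match="6"):
            model.predict(np.zeros((2, 4)))

    def test_predict_empty_and_repeated_rows(self):
        model = build_model(ModelConfig(input_dim=3, seed=1))
        assert predict(model, np.empty((0, 3))).shape == (0,)
        row = np.array([[0.1, 0.2, 0.3]])
        reps = predict(model, np.repeat(row, 5, axis=0))
        assert np.ptp(reps) == 0.0


class TestBackprop:
    @pytest.mark.parametrize("loss_kind,a", [("mse", 0.0), ("moorle", 3.0)])
    def test_weight_gradients_match_central_difference(self, loss_kind, a):
        """End-to-end d(loss)/d(weights) through the network and the loss."""
        rng = np.random.default_rng(3)
        model = build_model(
            ModelConfig(input_dim=4, hidden_layer_sizes=(5, 3), dropout_rate=0.0, seed=2)
        )
        X = rng.normal(size=(12, 4))
        y = rng.normal(0.5, 0.2, size=12)
        groups = np.array(["A", "B", "C"] * 4)
        cfg = LossConfig(loss_kind, a)

        def loss_value() -> float:
            preds = model.forward(X, training=False)
            batch = GroupedBatch(targets=y, group_labels=groups, predictions=preds)
            return batch_loss_and_gradient(batch, cfg)[0]

        preds = model.forward(X, training=True, rng=rng)
        batch = GroupedBatch(targets=y, group_labels=groups, predictions=preds)
        _, grad_pred = batch_loss_and_gradient(batch, cfg)
        grads_w, grads_b = model.backward(grad_pred)

        eps = 1e-6
        for params, grads in ((model.weights, grads_w), (model.biases, grads_b)):
            for p, g in zip(params, grads):
                flat = p.ravel()
                n_checks = min(5, flat.size)
                for idx in np.random.default_rng(0).choice(
                    flat.size, n_checks, replace=False
                ):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up = loss_value()
                    flat[idx] = orig - eps
                    down = loss_value()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    assert g.ravel()[idx] == pytest.approx(
                        numeric, rel=1e-4, abs=1e-7
                    )


class TestTrainModel:
    def test_learns_noiseless_linear_function(self):
        X, y, groups = linear_dataset(noise=0.0)
        model = build_model(
            ModelConfig(input_dim=6, hidden_layer_sizes=(32,), dropout_rate=0.0, seed=0)
        )
        result = train_model(
            model,
            X,
            y,
            groups,
            np.arange(len(y)),
            SamplerConfig(strategy="sequential", batch_size=32, seed=0),
            LossConfig("mse"),
            TrainConfig(epochs=200, learning_rate=3e-3, seed=0),
        )
        assert result.history[-1]["train_mse"] < 1e-2

    def test_history_length(self):
        X, y, groups = linear_dataset(n=40)
        model = build_model(ModelConfig(input_dim=6, hidden_layer_sizes=(8,), seed=0))
        result = train_model(
            model,
            X,
            y,
            groups,
            np.arange(40),
            SamplerConfig(batch_size=16, seed=0),
            LossConfig("mse"),
            TrainConfig(epochs=5, seed=0),
        )
        assert [h["epoch"] for h in result.history] == list(range(5))

    def test_full_run_determinism(self):
        X, y, groups = linear_dataset(n=60, noise=0.05)

        def run() -> np.ndarray:
            model = build_model(
                ModelConfig(input_dim=6, hidden_layer_sizes=(16,), seed=3)
            )
            train_model(
                model,
                X,
                y,
                groups,
                np.arange(60),
                SamplerConfig(strategy="mixed", batch_size=16, seed=4),
                LossConfig("moorle", 2.0),
                TrainConfig(epochs=8, seed=5),
            )
            return model.predict(X)

        np.testing.assert_array_equal(run(), run())

    def test_single_drug_moorle_equals_mse_trajectory(self):
        """With |D| = 1 the MOORLE regularizer vanishes identically, so the
        two losses must produce bit-identical training trajectories."""
        X, y, _ = linear_dataset(n=50, noise=0.05, seed=7)
        groups = np.array(["onlydrug"] * 50)

        def run(loss_cfg: LossConfig):
            model = build_model(
                ModelConfig(input_dim=6, hidden_layer_sizes=(12,), seed=1)
            )
            result = train_model(
                model,
                X,
                y,
                groups,
                np.arange(50),
                SamplerConfig(batch_size=16, seed=2),
                loss_cfg,
                TrainConfig(epochs=6, seed=3),
            )
            return model, result.history

        m_mse, h_mse = run(LossConfig("mse"))
        m_moo, h_moo = run(LossConfig("moorle", 5.0))
        for ha, hb in zip(h_mse, h_moo):
            assert ha["train_loss"] == hb["train_loss"]
        for wa, wb in zip(m_mse.weights, m_moo.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_empty_training_set_error(self):
        X, y, groups = linear_dataset(n=10)
        model = build_model(ModelConfig(input_dim=6, seed=0))
        with pytest.raises(ValueError):
            train_model(
                model,
                X,
                y,
                groups,
                np.array([], dtype=int),
                SamplerConfig(),
                LossConfig("mse"),
                TrainConfig(),
            )

    def test_early_stopping_restores_best(self):
        X, y, groups = linear_dataset(n=100, noise=0.1)
        model = build_model(
            ModelConfig(input_dim=6, hidden_layer_sizes=(8,), dropout_rate=0.0, seed=0)
        )
        result = train_model(
            model,
            X,
            y,
            groups,
            np.arange(80),
            SamplerConfig(batch_size=20, seed=0),
            LossConfig("mse"),
            TrainConfig(epochs=50, early_stop_patience=3, seed=0),
            val_indices=np.arange(80, 100),
        )
        assert len(result.history) <= 50
        assert "val_mse" in result.history[-1]


class TestStandardizer:
    def test_zero_mean_unit_variance_on_fit_portion(self, rng):
        X = rng.normal(3.0, 2.5, size=(50, 4))
        scaler = Standardizer().fit(X)
        Z = scaler.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_passthrough(self):
        X = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        Z = Standardizer().fit(X).transform(X)
        assert np.all(Z[:, 0] == 0.0)
        assert np.all(np.isfinite(Z))


class TestLossBalancingMechanism:
    def test_moorle_equalizes_conflicting_group_losses(self):
        """When a limited-capacity model must trade off two drugs with
        conflicting optimal fits and an 90/10 count imbalance, plain MSE
        sacrifices the rare drug; the entropy regularizer equalizes the
        per-drug losses and improves the drug-averaged error."""
        rng = np.random.default_rng(0)
        n_common, n_rare = 90, 10
        X = rng.normal(size=(n_common + n_rare, 1))
        # common drug wants y = +x, rare drug wants y = -x
        y = np.concatenate([X[:n_common, 0], -X[n_common:, 0]]) * 0.3 + 0.5
        groups = np.array(["common"] * n_common + ["rare"] * n_rare)

        def run(loss_cfg: LossConfig) -> dict[str, float]:
            model = build_model(
                ModelConfig(input_dim=1, hidden_layer_sizes=(4,), dropout_rate=0.0, seed=1)
            )
            train_model(
                model,
                X,
                y,
                groups,
                np.arange(len(y)),
                SamplerConfig(batch_size=len(y), seed=0),
                loss_cfg,
                TrainConfig(epochs=300, learning_rate=0.01, seed=0),
            )
            preds = model.predict(X)
            return {
                g: float(np.mean((preds[groups == g] - y[groups == g]) ** 2))
                for g in ("common", "rare")
            }

        mse_fit = run(LossConfig("mse"))
        moorle_fit = run(LossConfig("moorle", 2.0))
        # MSE sacrifices the rare drug
        assert mse_fit["rare"] > 5 * mse_fit["common"]
        # MOORLE equalizes the per-drug losses ...
        ratio = moorle_fit["rare"] / moorle_fit["common"]
        assert 1 / 2 < ratio < 2
        # ... and improves the drug-averaged (equal-weight) error
        assert sum(moorle_fit.values()) / 2 < sum(mse_fit.values()) / 2
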