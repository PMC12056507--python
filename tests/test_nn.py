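"""Network contracts: shapes, losses, LR schedule, optimizers,
gradients, early stopping and training determinism."""

import math

import numpy as np
import pytest

import spheroidseg as ss
from spheroidseg.nn import (
    ModelConfig,
    TrainConfig,
    build_model,
    cross_entropy_loss,
    dice_loss,
    focal_loss,
    one_cycle_schedule,
    predict_probmap,
    train,
)
from spheroidseg.nn.losses import loss_and_grad
from spheroidseg.nn.model import softmax2


class TestModel:
    def test_output_shape_matches_input(self):
        model = build_model(ModelConfig(depth=3, base_channels=8, input_size=(128, 128)))
        x = np.random.default_rng(0).random((1, 128, 128, 1), dtype=np.float32)
        logits = model.forward(x)
        assert logits.shape == (1, 128, 128, 2)

    def test_softmax_probabilities_normalized(self):
        model = build_model(ModelConfig(depth=2, base_channels=4, input_size=(32, 32)))
        x = np.random.default_rng(1).random((2, 32, 32, 1), dtype=np.float32)
        p = softmax2(model.forward(x))
        assert p.min() >= 0 and p.max() <= 1
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, rtol=1e-5)

    def test_parameter_count_grows_with_base_channels(self):
        counts = [
            build_model(ModelConfig(depth=3, base_channels=b, input_size=(64, 64))).n_parameters()
            for b in (4, 8, 16)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(depth=3, base_channels=8, input_size=(100, 100))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(ModelConfig(depth=2, base_channels=4, input_size=(16, 16)), seed=3)
        model.trained = True
        model.save(tmp_path / "ckpt.npz")
        back = type(model).load(tmp_path / "ckpt.npz")
        x = np.random.default_rng(2).random((1, 16, 16, 1), dtype=np.float32)
        np.testing.assert_array_equal(model.forward(x), back.forward(x))
        assert back.trained


class TestLosses:
    def test_perfect_predictions_near_zero(self):
        t = np.random.default_rng(0).random((32, 32)) < 0.5
        p = t.astype(float)
        assert dice_loss(p, t) < 2e-3  # ε-order
        assert cross_entropy_loss(p, t) < 1e-5
        assert focal_loss(p, t) < 1e-5

    def test_total_mismatch_dice_near_one(self):
        t = np.zeros((16, 16), bool)
        t[:8] = True
        assert dice_loss(1.0 - t.astype(float), t) > 0.99

    def test_uniform_half_dice(self):
        t = np.zeros((64, 64), bool)
        t[:32] = True  # |T| = half the pixels
        p = np.full((64, 64), 0.5)
        assert dice_loss(p, t, eps=0.0) == pytest.approx(0.5, abs=1e-12)

    def test_focal_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(3)
        p = rng.random((20, 20))
        t = rng.random((20, 20)) < 0.4
        assert focal_loss(p, t, gamma=0.0) == pytest.approx(cross_entropy_loss(p, t), rel=1e-12)

    def test_focal_single_pixel_closed_form(self):
        p = np.array([[0.5]])
        t = np.array([[True]])
        assert focal_loss(p, t, gamma=2.0) == pytest.approx(0.25 * math.log(2), rel=1e-9)

    def test_losses_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random((10, 10))
            t = rng.random((10, 10)) < 0.5
            assert dice_loss(p, t) >= 0
            assert cross_entropy_loss(p, t) >= 0
            assert focal_loss(p, t) >= 0

    @pytest.mark.parametrize("loss", ["dice", "ce", "focal"])
    def test_gradients_match_finite_differences(self, loss):
        rng = np.random.default_rng(5)
        model = build_model(ModelConfig(depth=2, base_channels=4, input_size=(16, 16)), seed=1)
        x = rng.random((1, 16, 16, 1), dtype=np.float32)
        t = rng.random((1, 16, 16)) > 0.5
        model.zero_grad()
        _, dlog = loss_and_grad(loss, model.forward(x), t)
        model.backward(dlog)
        grads = model.gradients()
        params = model.parameters()
        for key in ("l0.W", "l2.b", "l4.W"):
            p, g = params[key], grads[key]
            idx = tuple(rng.integers(s) for s in p.shape)
            eps = 1e-3
            old = p[idx]
            p[idx] = old + eps
            lp, _ = loss_and_grad(loss, model.forward(x), t)
            p[idx] = old - eps
            lm, _ = loss_and_grad(loss, model.forward(x), t)
            p[idx] = old
            numeric = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(numeric, rel=0.08, abs=2e-4)


class TestOneCycle:
    def test_boundaries_and_midpoint(self):
        lr = one_cycle_schedule((1e-3, 1e-2), 100)
        assert lr(0) == pytest.approx(1e-3)
        assert lr(50) == pytest.approx(1e-2)
        assert lr(100) == pytest.approx(1e-3)

    def test_quarter_point_is_linear_midpoint(self):
        lr = one_cycle_schedule((2e-4, 1e-3), 200)
        assert lr(50) == pytest.approx((2e-4 + 1e-3) / 2)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            one_cycle_schedule((1e-2, 1e-3), 10)


def _toy_items(n, seed, **synth_kw):
    cfg = ss.synth.desk_scale_config(seed=seed, image_size=(64, 64), **synth_kw)
    return [
        (s.image, s.target, s.spheroid_id)
        for s in (ss.generate_sample(cfg, i, spheroid_id=f"T{seed}_{i}") for i in range(n))
    ]


class TestTrain:
    def test_leakage_rejected_before_training(self):
        items = _toy_items(4, seed=0)
        model = build_model(ModelConfig(depth=2, base_channels=4, input_size=(64, 64)))
        with pytest.raises(ValueError, match="leakage"):
            train(model, items, items[:2], TrainConfig(epochs=2, patience=1, seed=0))

    def test_early_stopping_on_non_improving_metric(self):
        items = _toy_items(2, seed=1)
        val = _toy_items(2, seed=2)
        model = build_model(ModelConfig(depth=2, base_channels=4, input_size=(64, 64)))
        seq = iter(range(100))  # strictly worsening after the first epoch

        def stub_metric(_model):
            return 0.5 + next(seq) * 0.01

        hist = train(
            model, items, val,
            TrainConfig(epochs=20, patience=3, seed=0, augment=False),
            val_metric=stub_metric,
        )
        # best at epoch 1, then `patience` non-improving epochs, stop
        assert len(hist.rows) == 4
        assert hist.best_epoch == 1

    def test_same_seed_reproduces_history(self):
        items = _toy_items(3, seed=3)
        val = _toy_items(2, seed=4)
        cfgs = TrainConfig(epochs=2, patience=2, seed=7, augment=True, batch_size=2)
        h1 = train(build_model(ModelConfig(depth=2, base_channels=4, input_size=(64, 64)), seed=7), items, val, cfgs)
        h2 = train(build_model(ModelConfig(depth=2, base_channels=4, input_size=(64, 64)), seed=7), items, val, cfgs)
        assert h1.rows == h2.rows

    def test_early_stopping_never_sees_training_ids(self):
        items = _toy_items(3, seed=5)
        val = _toy_items(2, seed=6)
        model = build_model(ModelConfig(depth=2, base_channels=4, input_size=(64, 64)))
        hist = train(model, items, val, TrainConfig(epochs=2, patience=2, seed=0, augment=False))
        assert hist.train_ids.isdisjoint(hist.val_ids)

    def test_overfits_clean_images(self):
        # small clean set, many epochs: the network must drive its
        # training-set segmentation error to (near) zero
        items = _toy_items(4, seed=8, debris_extent_factor=0.0, debris_opacity=0.0)
        val = _toy_items(2, seed=9, debris_extent_factor=0.0, debris_opacity=0.0)
        model = build_model(ModelConfig(depth=3, base_channels=8, input_size=(64, 64)), seed=0)
        train(model, items, val, TrainConfig(epochs=60, patience=60, seed=0, augment=False))
        from spheroidseg.nn.train import validation_jcd

        train_jcd = validation_jcd(model, items, 1.0)
        assert train_jcd <= 0.1

    def test_predict_probmap_contract(self):
        cfg = ss.synth.desk_scale_config(seed=10, image_size=(96, 96))
        s = ss.generate_sample(cfg, 0)
        model = build_model(ModelConfig(depth=3, base_channels=4, input_size=(48, 48)))
        pm = predict_probmap(model, s.image, resize_factor=0.5)
        assert pm.values.shape == s.image.shape  # native grid regardless of factor
        assert pm.values.min() >= 0 and pm.values.max() <= 1
        assert pm.trained is False  # untrained model flagged
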