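"""Losses, layers and the fused UNet: closed forms, gradients, training."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dualifc.data import Dataset
from dualifc.nn import (
    ArchConfig,
    FusedUNet,
    TrainingConfig,
    desk_config,
    grad_logits,
    grad_recon,
    loss_ce,
    loss_mse,
    loss_total,
    softmax,
    train,
)
from dualifc.nn.layers import AdaptiveAvgPool, Affine, ConvND, MaxPool, ReLU, Upsample
from dualifc.nn.unet import UNetBranch


class TestSoftmax:
    def test_symmetry_and_normalization(self):
        np.testing.assert_allclose(softmax(np.array([[0.0, 0.0]])), [[0.5, 0.5]])

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(5, 3))
        np.testing.assert_allclose(softmax(logits), softmax(logits + 7.3), atol=1e-12)

    def test_two_zero_example(self):
        out = softmax(np.array([[2.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.880797, 0.119203]], atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        assert np.allclose(softmax(rng.normal(size=(10, 4))).sum(axis=1), 1, atol=1e-6)


class TestLosses:
    def test_perfect_prediction_zero_ce(self):
        y = np.eye(2)
        assert loss_ce(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_ln2(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        assert loss_ce(y, p) == pytest.approx(np.log(2))

    def test_two_sample_batch_average(self):
        """Batch {1.0, 0.5} at the true class: (0 + ln 2)/2."""
        y = np.eye(2)
        p = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert loss_ce(y, p) == pytest.approx(np.log(2) / 2)

    def test_mse_zero_for_identical(self, rng):
        x2 = rng.random((3, 1, 8, 8))
        x3 = rng.random((3, 1, 4, 4, 4))
        assert loss_mse(x2, x2, x3, x3, 0.5) == 0.0

    def test_mse_weighting_closed_form(self, rng):
        x2 = rng.random((2, 1, 8, 8))
        x3 = rng.random((2, 1, 4, 4, 4))
        d2, d3 = 0.3, 0.1
        full = loss_mse(x2, x2 + d2, x3, x3 + d3, 0.5)
        assert full == pytest.approx(0.5 * d2**2 + 0.5 * d3**2)
        only2d = loss_mse(x2, x2 + d2, x3, x3 + d3, 1.0)
        assert only2d == pytest.approx(d2**2)

    def test_total_loss_decomposition(self):
        assert loss_total(0.6931, 0.01, 0.5) == pytest.approx(0.35155)
        assert loss_total(1.0, 2.0, 1.0) == 1.0
        assert loss_total(1.0, 2.0, 0.0) == 2.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            loss_mse(np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2)), 1.5)
        with pytest.raises(ValueError):
            loss_total(1.0, 1.0, -0.1)


def finite_difference_check(layer_params, loss_fn, eps=1e-5, rel_tol=1e-4, max_checks=6):
    """Compare analytic gradients with central differences on a sample of weights."""
    rng = np.random.default_rng(0)
    for p, g in layer_params:
        flat_idx = rng.choice(p.size, size=min(max_checks, p.size), replace=False)
        for idx in flat_idx:
            orig = p.flat[idx]
            p.flat[idx] = orig + eps
            up = loss_fn()
            p.flat[idx] = orig - eps
            down = loss_fn()
            p.flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            analytic = g.flat[idx]
            denom = max(abs(numeric), abs(analytic), 1e-8)
            assert abs(numeric - analytic) / denom < rel_tol, (
                f"grad mismatch: numeric {numeric}, analytic {analytic}"
            )


class TestLayerGradients:
    def _check_layer(self, layer, x, rng):
        target = rng.standard_normal(layer.forward(x)[0].shape)

        def loss():
            y, _ = layer.forward(x)
            return 0.5 * ((y - target) ** 2).sum()

        y, cache = layer.forward(x)
        layer.zero_grad()
        layer.backward(y - target, cache)
        finite_difference_check(list(zip(layer.params, layer.grads)), loss)

    def test_conv2d_weight_gradients(self, rng):
        layer = ConvND(2, 3, ndim=2, kernel_size=3, rng=rng, dtype=np.float64)
        self._check_layer(layer, rng.standard_normal((2, 2, 6, 6)), rng)

    def test_conv3d_weight_gradients(self, rng):
        layer = ConvND(1, 2, ndim=3, kernel_size=3, rng=rng, dtype=np.float64)
        self._check_layer(layer, rng.standard_normal((2, 1, 4, 4, 4)), rng)

    def test_affine_weight_gradients(self, rng):
        layer = Affine(7, 3, rng=rng, dtype=np.float64)
        self._check_layer(layer, rng.standard_normal((4, 7)), rng)

    def test_conv_input_gradients(self, rng):
        """dx of the conv equals central differences through a scalar loss."""
        layer = ConvND(1, 2, ndim=2, kernel_size=3, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 1, 5, 5))
        target = rng.standard_normal(layer.forward(x)[0].shape)
        y, cache = layer.forward(x)
        layer.zero_grad()
        dx = layer.backward(y - target, cache)
        eps = 1e-6
        for idx in [(0, 0, 2, 2), (0, 0, 0, 0), (0, 0, 4, 3)]:
            orig = x[idx]
            x[idx] = orig + eps
            up = 0.5 * ((layer.forward(x)[0] - target) ** 2).sum()
            x[idx] = orig - eps
            down = 0.5 * ((layer.forward(x)[0] - target) ** 2).sum()
            x[idx] = orig
            assert dx[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-5)

    def test_pool_upsample_roundtrip_shapes(self, rng):
        x = rng.standard_normal((2, 3, 8, 8, 8))
        pool = MaxPool(3)
        up = Upsample(3)
        y, c = pool.forward(x)
        assert y.shape == (2, 3, 4, 4, 4)
        assert pool.backward(y, c).shape == x.shape
        z, cu = up.forward(y)
        assert z.shape == x.shape
        assert up.backward(z, cu).shape == y.shape

    def test_adaptive_pool_averages_blocks(self):
        x = np.arange(16.0).reshape(1, 1, 4, 4)
        y, _ = AdaptiveAvgPool(2, 2).forward(x)
        np.testing.assert_allclose(y[0, 0], [[2.5, 4.5], [10.5, 12.5]])


class TinyFused(FusedUNet):
    """Full fused model at toy spatial scale for gradient checking."""

    def __init__(self, seed=0):
        arch = ArchConfig(depth=2, base_channels_2d=2, base_channels_3d=2,
                          latent_grid=2, n_classes=2, dtype=np.float64)
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.branch2d = UNetBranch(2, 8, 2, 2, 2, rng, np.float64)
        self.branch3d = UNetBranch(3, 8, 2, 2, 2, rng, np.float64)
        self.classifier = Affine(
            self.branch2d.latent_dim + self.branch3d.latent_dim, 2, rng, np.float64
        )


class TestFusedModelGradients:
    def test_total_loss_gradients_match_finite_differences(self, rng):
        """Analytic backprop through both branches, skips, latent fusion and
        all three loss terms agrees with central differences to < 1e-4."""
        model = TinyFused(seed=1)
        x2 = rng.random((2, 1, 8, 8))
        x3 = rng.random((2, 1, 8, 8, 8))
        y = np.eye(2)
        w1 = w2 = 0.5

        def total():
            logits, r2, r3, _ = model.forward(x2, x3)
            return loss_total(
                loss_ce(y, softmax(logits)), loss_mse(x2, r2, x3, r3, w1), w2
            )

        logits, r2, r3, cache = model.forward(x2, x3)
        probs = softmax(logits)
        model.zero_grad()
        model.backward(
            grad_logits(y, probs, w2),
            grad_recon(x2, r2, w1, w2),
            grad_recon(x3, r3, 1 - w1, w2),
            cache,
        )
        finite_difference_check(
            list(zip(model.params, model.grads)), total, eps=1e-6, rel_tol=1e-4, max_checks=4
        )

    def test_decoder_outputs_match_input_shapes(self, rng):
        model = FusedUNet(ArchConfig(base_channels_2d=2, base_channels_3d=1), seed=0)
        x2 = rng.random((2, 1, 80, 80)).astype(np.float32)
        x3 = rng.random((2, 1, 40, 40, 40)).astype(np.float32)
        logits, recon2, recon3, _ = model.forward(x2, x3)
        assert recon2.shape == x2.shape
        assert recon3.shape == x3.shape
        assert logits.shape == (2, 2)
        assert np.allclose(softmax(logits).sum(axis=1), 1, atol=1e-6)


def tiny_dataset(n_per_class=12, seed=0) -> Dataset:
    """Trivially separable cohort: bright blob upper-left vs lower-right."""
    rng = np.random.default_rng(seed)
    n = n_per_class * 2
    t = np.zeros((n, 80, 80), dtype=np.float32)
    s = np.zeros((n, 40, 40, 40), dtype=np.float32)
    labels = []
    for i in range(n):
        healthy = i % 2 == 0
        pos2, pos3 = ((10, 30), (5, 15)) if healthy else ((50, 70), (25, 35))
        t[i, pos2[0]:pos2[1], pos2[0]:pos2[1]] = 1.0
        s[i, pos3[0]:pos3[1], pos3[0]:pos3[1], pos3[0]:pos3[1]] = 1.0
        t[i] += rng.random((80, 80)).astype(np.float32) * 0.1
        s[i] += rng.random((40, 40, 40)).astype(np.float32) * 0.1
        labels.append("healthy" if healthy else "diseased")
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "subject_id": ["S1"] * n,
            "cell_type": ["HSC"] * n,
            "label": labels,
        }
    )
    return Dataset(transmission=t, ssc=s, meta=meta)


class TestTraining:
    def test_lr_schedule_and_loss_decrease(self):
        """LR trace: initial rate for warm-up epochs then the raised rate;
        training loss drops on an easy set."""
        ds = tiny_dataset()
        model = FusedUNet(
            ArchConfig(depth=2, base_channels_2d=2, base_channels_3d=1, latent_grid=5), seed=0
        )
        config = TrainingConfig(
            epochs=7, lr_initial=1e-3, lr_raised=5e-3, warmup_epochs=5,
            batch_size=8, conventional_betas=True, seed=0,
        )
        history = train(model, ds, ds, config)
        assert history["lr"][:5] == [1e-3] * 5
        assert history["lr"][5] == 5e-3
        assert history["loss"][-1] < history["loss"][0]
        for total, ce, mse in zip(history["loss"], history["ce"], history["mse"]):
            assert total == pytest.approx(0.5 * ce + 0.5 * mse, abs=1e-9)

    def test_training_is_deterministic(self):
        ds = tiny_dataset(n_per_class=6)
        arch = ArchConfig(depth=2, base_channels_2d=1, base_channels_3d=1, latent_grid=5)
        config = desk_config(seed=3, epochs=2)
        h1 = train(FusedUNet(arch, seed=3), ds, ds, config)
        h2 = train(FusedUNet(arch, seed=3), ds, ds, config)
        assert h1 == h2

    def test_paper_defaults_recorded(self):
        config = TrainingConfig()
        assert config.epochs == 50
        assert config.lr_initial == 1e-5
        assert config.lr_raised == 5e-5
        assert config.warmup_epochs == 5
        assert config.betas == (0.99, 0.9999)
        assert TrainingConfig(conventional_betas=True).betas == (0.9, 0.999)
        assert config.plateau_patience == 5
        assert config.plateau_factor == 0.5
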