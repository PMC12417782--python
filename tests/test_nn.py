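"""CNN mechanics: gradients vs numeric differentiation, identity-at-init,
shape bookkeeping, schedule, training contracts."""

import numpy as np
import pytest

from ramanline import CNNConfig, RamanCNN, TrainConfig, build_model, lr_schedule
from ramanline.augment import AugmentConfig
from ramanline.nn import AdamW, load_checkpoint, save_checkpoint, train


class TestArchitecture:
    def test_output_shape_two_targets(self, rng):
        model = RamanCNN(CNNConfig(), rng=0)
        out = model.forward(rng.normal(size=(4, 2048)))
        assert out.shape == (4, 2)

    def test_spatial_length_8_after_8_blocks(self):
        # 2048 / 2^8 == 8: run forward and inspect the pre-pooling feature map
        model = RamanCNN(CNNConfig(), rng=0)
        model.forward(np.zeros((1, 2048)), train=True)
        tag, h_last, _ = model._cache[-1]
        assert tag == "head"
        assert h_last.shape[-1] == 8

    def test_channel_schedule_doubles_every_two_blocks(self):
        cfg = CNNConfig()
        assert cfg.channel_schedule() == [16, 16, 32, 32, 64, 64, 128, 128, 128]

    def test_incompatible_length_rejected(self):
        model = RamanCNN(CNNConfig(), rng=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 2050)))
        with pytest.raises(ValueError, match="divisible"):
            build_model(CNNConfig(), input_length=1000)

    def test_zero_residual_scales_make_blocks_identity(self, rng):
        """At init every conv path is gated off: perturbing its weights
        cannot change the output."""
        model = RamanCNN(CNNConfig(), rng=0)
        x = rng.normal(size=(3, 2048))
        before = model.forward(x)
        for i in range(model.config.n_blocks):
            model.params[f"b{i}_dw"] = model.params[f"b{i}_dw"] + 5.0
            model.params[f"b{i}_pw"] = model.params[f"b{i}_pw"] - 3.0
        after = model.forward(x)
        np.testing.assert_array_equal(before, after)


class TestGradients:
    def test_backward_matches_numeric_gradient(self, rng):
        cfg = CNNConfig(n_blocks=2, base_channels=4, channel_cap=8,
                        kernel_size=5, n_targets=2)
        model = RamanCNN(cfg, rng=0, dtype=np.float64)
        for key in model.params:  # open the residual gates so every path counts
            if key.endswith("_alpha"):
                model.params[key] = np.asarray(0.7)
        x = rng.normal(size=(3, 16))
        y = rng.normal(size=(3, 2))

        def loss():
            pred = model.forward(x, train=True)
            return float(np.mean((pred - y) ** 2)), pred

        _, pred = loss()
        grads = model.backward(2 * (pred - y) / pred.size)
        eps = 1e-6
        for name, p in model.params.items():
            numeric = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + eps
                lp, _ = loss()
                p[i] = orig - eps
                lm, _ = loss()
                p[i] = orig
                numeric[i] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(grads[name], numeric, rtol=1e-4, atol=1e-7)


class TestLRSchedule:
    def test_peak_reached_at_end_of_warmup(self):
        cfg = TrainConfig(peak_lr=1e-2, warmup_epochs=20)
        assert lr_schedule(20, cfg) == pytest.approx(1e-2)

    def test_ramp_starts_at_zero(self):
        cfg = TrainConfig(warmup_epochs=20)
        assert lr_schedule(0, cfg) == 0.0
        assert lr_schedule(10, cfg) == pytest.approx(cfg.peak_lr / 2)

    def test_exponential_decay_closed_form(self):
        cfg = TrainConfig(peak_lr=1.0, warmup_epochs=20, gamma=0.95)
        assert lr_schedule(30, cfg) == pytest.approx(0.95**10)
        assert lr_schedule(30, cfg) == pytest.approx(0.5987, abs=1e-4)


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = RamanCNN(CNNConfig(n_blocks=2, base_channels=4), rng=0)
        before = model.state_dict()
        history = train(model, rng.normal(size=(8, 64)), rng.normal(size=(8, 2)),
                        None, None, TrainConfig(epochs=0))
        assert len(history) == 0
        for key, value in model.params.items():
            np.testing.assert_array_equal(value, before[key])

    def test_empty_training_set_rejected(self):
        model = RamanCNN(CNNConfig(n_blocks=2, base_channels=4), rng=0)
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 64)), np.zeros((0, 2)), None, None,
                  TrainConfig(epochs=1))

    def test_fixed_seed_reproduces_final_loss(self, rng):
        x = rng.normal(size=(32, 64))
        y = rng.normal(size=(32, 2))

        def run():
            model = RamanCNN(CNNConfig(n_blocks=2, base_channels=4), rng=0)
            history = train(model, x, y, x, y,
                            TrainConfig(epochs=5, warmup_epochs=2, seed=3),
                            AugmentConfig())
            return history.val_loss[-1]

        assert run() == run()

    def test_learns_noise_free_linear_two_peak_problem(self, rng):
        """Validation MAE well below the label range on an easy toy task.

        Two analyte peaks plus a constant solvent reference band: the
        reference matters because per-spectrum SNV removes absolute scale,
        which only an internal reference can restore.
        """
        wn = np.linspace(0, 1, 256)
        peaks = np.stack([np.exp(-0.5 * ((wn - c) / 0.03) ** 2) for c in (0.3, 0.7)])
        reference = np.exp(-0.5 * ((wn - 0.5) / 0.05) ** 2)
        labels = rng.uniform(0.0, 1.0, size=(50, 2))
        x = labels @ peaks + reference
        x = (x - x.mean(1, keepdims=True)) / np.maximum(x.std(1, keepdims=True), 1e-9)
        model = RamanCNN(CNNConfig(n_blocks=4, base_channels=8, channel_cap=16), rng=0)
        cfg = TrainConfig(epochs=200, warmup_epochs=10, peak_lr=1e-2, gamma=0.995,
                          batch_size=16, seed=0)
        history = train(model, x[:40], labels[:40], x[40:], labels[40:], cfg)
        pred = model.forward(x[40:])
        mae = np.abs(pred - labels[40:]).mean()
        assert mae < 0.1  # 10% of the unit label range
        assert history.train_loss[-1] < history.train_loss[0]


def test_checkpoint_roundtrip(tmp_path, rng):
    model = RamanCNN(CNNConfig(n_blocks=2, base_channels=4), rng=0)
    x = rng.normal(size=(2, 64))
    path = tmp_path / "model.npz"
    save_checkpoint(path, model, {"note": "test"})
    restored, meta = load_checkpoint(path)
    assert meta["note"] == "test"
    np.testing.assert_array_equal(model.forward(x), restored.forward(x))


def test_adamw_decoupled_decay_shrinks_weights_only():
    params = {"w_w": np.ones(3), "w_b": np.ones(3)}
    opt = AdamW(params, weight_decay=0.5)
    grads = {"w_w": np.zeros(3), "w_b": np.zeros(3)}
    opt.step(params, grads, lr=0.1)
    assert np.all(params["w_w"] < 1.0)  # decayed
    np.testing.assert_array_equal(params["w_b"], np.ones(3))  # bias untouched
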