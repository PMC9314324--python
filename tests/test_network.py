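import numpy as np
import pytest

from qrskit import network
from qrskit.network import (
    AdamW,
    ModelConfig,
    TrainConfig,
    build_model,
    clip_grad_l2,
    cross_entropy,
    infer,
    load_model,
    save_model,
    softmax,
    train,
)
from qrskit.network._layers import (
    BatchNorm1d,
    Conv1d,
    GRU,
    PositionwiseLinear,
    ResBlock1d,
)


def small_config(**overrides):
    kwargs = dict(n_res_blocks=2, channels_per_block=[4, 8],
                  kernel_size=5, gru_hidden=8, seed=0)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


class TestModelConfig:
    def test_defaults_match_recipe(self):
        config = ModelConfig()
        assert config.n_res_blocks == 5
        assert config.n_classes == 4

    def test_channel_mismatch(self):
        with pytest.raises(ValueError):
            ModelConfig(n_res_blocks=3, channels_per_block=[8, 8])

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            small_config(kernel_size=6)

    def test_n_classes_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=3)


class TestShapes:
    @pytest.mark.parametrize("length", [100, 1000, 3000])
    def test_length_preserved(self, length, rng):
        model = build_model(small_config())
        x = rng.standard_normal((2, 1, length))
        assert model.forward(x).shape == (2, 4, length)

    def test_default_depth_preserves_length(self, rng):
        model = build_model(ModelConfig(
            channels_per_block=[4, 4, 4, 4, 4], gru_hidden=4, seed=0))
        x = rng.standard_normal((1, 1, 200))
        assert model.forward(x).shape == (1, 4, 200)

    def test_bidirectional_shape(self, rng):
        model = build_model(small_config(gru_bidirectional=True))
        x = rng.standard_normal((1, 1, 150))
        assert model.forward(x).shape == (1, 4, 150)

    def test_input_validation(self):
        model = build_model(small_config())
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 3, 100)))


class TestInfer:
    def test_columns_sum_to_one(self, rng):
        model = build_model(small_config())
        mask = infer(model, rng.standard_normal(500))
        assert mask.shape == (4, 500)
        np.testing.assert_allclose(mask.sum(axis=0), 1.0, atol=1e-5)
        assert np.all((mask >= 0) & (mask <= 1))

    def test_deterministic_in_eval(self, rng):
        model = build_model(small_config())
        x = rng.standard_normal(300)
        np.testing.assert_array_equal(infer(model, x), infer(model, x))

    def test_zeroed_head_gives_uniform(self, rng):
        model = build_model(small_config())
        model.fc.weight.value[...] = 0.0
        model.fc.bias.value[...] = 0.0
        mask = infer(model, rng.standard_normal(200))
        np.testing.assert_allclose(mask, 0.25, atol=1e-6)

    def test_nonfinite_rejected(self):
        model = build_model(small_config())
        with pytest.raises(ValueError):
            infer(model, np.array([1.0, np.nan] * 100))


class TestDeterminism:
    def test_same_seed_same_init(self):
        a = build_model(small_config(seed=5))
        b = build_model(small_config(seed=5))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_different_seed_different_init(self):
        a = build_model(small_config(seed=5))
        b = build_model(small_config(seed=6))
        assert any(
            not np.array_equal(pa.value, pb.value)
            for pa, pb in zip(a.params(), b.params())
        )


# ---------------------------------------------------------------------------
# Numerical gradient checks: central differences on a scalar loss vs the
# analytic backward pass, layer by layer.  Done in float32, so tolerances
# are loose but still catch transposition/sign errors.
# ---------------------------------------------------------------------------

def _num_grad_check(layer, x, rng, atol=2e-2, n_entries=6, train=True):
    y = layer.forward(x.astype(np.float32), train=train)
    w = rng.standard_normal(y.shape).astype(np.float32)

    def loss_of(xp):
        return float(np.sum(layer.forward(xp.astype(np.float32), train=train) * w))

    for p in layer.params():
        p.zero_grad()
    layer.forward(x.astype(np.float32), train=train)
    dx = layer.backward(w)

    eps = 1e-2
    flat_x = x.reshape(-1)
    for idx in rng.choice(flat_x.size, size=min(n_entries, flat_x.size),
                          replace=False):
        xp = flat_x.copy()
        xp[idx] += eps
        up = loss_of(xp.reshape(x.shape))
        xp[idx] -= 2 * eps
        down = loss_of(xp.reshape(x.shape))
        numeric = (up - down) / (2 * eps)
        assert dx.reshape(-1)[idx] == pytest.approx(numeric, abs=atol)

    for p in layer.params():
        flat = p.value.reshape(-1)
        gflat = p.grad.reshape(-1)
        for idx in rng.choice(flat.size, size=min(n_entries, flat.size),
                              replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_of(x)
            flat[idx] = orig - eps
            down = loss_of(x)
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert gflat[idx] == pytest.approx(numeric, abs=atol)


class TestGradients:
    def test_conv1d(self, rng):
        layer = Conv1d(3, 5, 3, rng)
        _num_grad_check(layer, rng.standard_normal((2, 3, 12)), rng)

    def test_batchnorm(self, rng):
        layer = BatchNorm1d(3)
        layer.momentum = 0.0  # keep running stats fixed during the check
        _num_grad_check(layer, rng.standard_normal((2, 3, 10)), rng)

    def test_gru(self, rng):
        layer = GRU(3, 4, rng)
        _num_grad_check(layer, rng.standard_normal((2, 3, 7)), rng)

    def test_gru_reverse(self, rng):
        layer = GRU(3, 4, rng, reverse=True)
        _num_grad_check(layer, rng.standard_normal((2, 3, 7)), rng)

    def test_linear(self, rng):
        layer = PositionwiseLinear(4, 3, rng)
        _num_grad_check(layer, rng.standard_normal((2, 4, 9)), rng)

    def test_res_block(self, rng):
        """Statistical check: finite differences can straddle ReLU kinks,
        so require a tiny median error and allow rare outliers."""
        layer = ResBlock1d(2, 4, 3, rng)
        layer.bn1.momentum = 0.0
        layer.bn2.momentum = 0.0
        x = rng.standard_normal((2, 2, 11)).astype(np.float32)
        w = rng.standard_normal((2, 4, 11)).astype(np.float32)

        def loss():
            return float(np.sum(layer.forward(x, train=True) * w))

        for p in layer.params():
            p.zero_grad()
        layer.forward(x, train=True)
        layer.backward(w)
        eps = 1e-3
        errors = []
        for p in layer.params():
            flat = p.value.reshape(-1)
            grads = p.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=min(10, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                errors.append(abs((up - down) / (2 * eps) - grads[idx]))
        errors = np.array(errors)
        assert np.median(errors) < 5e-3
        assert np.mean(errors > 5e-2) < 0.1

    def test_cross_entropy_gradient(self, rng):
        logits = rng.standard_normal((2, 4, 6))
        targets = rng.integers(0, 4, (2, 6))
        _, dlogits = cross_entropy(logits, targets)
        eps = 1e-4
        for _ in range(6):
            b = rng.integers(0, 2)
            c = rng.integers(0, 4)
            l = rng.integers(0, 6)
            lp = logits.copy()
            lp[b, c, l] += eps
            up, _ = cross_entropy(lp, targets)
            lp[b, c, l] -= 2 * eps
            down, _ = cross_entropy(lp, targets)
            numeric = (up - down) / (2 * eps)
            assert dlogits[b, c, l] == pytest.approx(numeric, abs=1e-4)


class TestClipping:
    def test_norm_5_clipped_to_1(self, rng):
        model = build_model(small_config())
        params = model.params()
        # fabricate gradients with global L2 norm exactly 5
        total = sum(p.grad.size for p in params)
        fill = 5.0 / np.sqrt(total)
        for p in params:
            p.grad[...] = fill
        pre = clip_grad_l2(params, 1.0)
        assert pre == pytest.approx(5.0, rel=1e-5)
        post = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                           for p in params))
        assert post == pytest.approx(1.0, rel=1e-5)

    def test_small_gradient_untouched(self, rng):
        model = build_model(small_config())
        params = model.params()
        for p in params:
            p.grad[...] = 1e-6
        before = [p.grad.copy() for p in params]
        clip_grad_l2(params, 1.0)
        for p, b in zip(params, before):
            np.testing.assert_array_equal(p.grad, b)


class TestSoftmax:
    def test_uniform_for_zeros(self):
        out = softmax(np.zeros((1, 4, 5)), axis=1)
        np.testing.assert_allclose(out, 0.25)

    def test_stable_for_large_logits(self):
        out = softmax(np.array([[[1000.0], [0.0], [0.0], [0.0]]]), axis=1)
        assert np.isfinite(out).all()


class _ArrayBatchSampler:
    """Fixed-batch sampler for tiny training tests."""

    def __init__(self, signals, targets):
        self.signals, self.targets = signals, targets

    def __len__(self):
        return self.signals.shape[0]

    def sample_batch(self, batch_size):
        return self.signals, self.targets


def _toy_problem(rng, n_windows=4, length=400):
    """Windows where the target is recoverable from the signal sign."""
    signals = np.zeros((n_windows, 1, length))
    targets = np.zeros((n_windows, length), dtype=np.int64)
    for w in range(n_windows):
        for start in range(20, length - 20, 80):
            cls = int(rng.integers(1, 4))
            targets[w, start : start + 10] = cls
            bump = np.sin(np.linspace(0, np.pi, 10)) * (2.0 + cls)
            signals[w, 0, start : start + 10] = bump * (1 if cls < 3 else -1)
        signals[w, 0] += 0.05 * rng.standard_normal(length)
        signals[w, 0] = (signals[w, 0] - signals[w, 0].mean()) / signals[w, 0].std()
    return signals, targets


class TestTraining:
    def test_loss_decreases_on_fixed_batch(self, rng):
        signals, targets = _toy_problem(rng)
        model = build_model(small_config())
        sampler = _ArrayBatchSampler(signals, targets)
        config = TrainConfig(epochs=1, batch_size=4, steps_per_epoch=30, seed=0)
        optimizer_losses = []
        params = model.params()
        opt = AdamW(params, lr=1e-3)
        for _ in range(30):
            logits = model.forward(signals, train=True)
            loss, dlogits = cross_entropy(logits, targets)
            optimizer_losses.append(loss)
            model.zero_grad()
            model.backward(dlogits)
            clip_grad_l2(params, 1.0)
            opt.step()
        assert min(optimizer_losses[1:]) < optimizer_losses[0]

    def test_overfit_single_batch(self, rng):
        """Capacity check: > 0.99 per-sample accuracy within 200 steps."""
        signals, targets = _toy_problem(rng)
        model = build_model(ModelConfig(
            n_res_blocks=3, channels_per_block=[8, 8, 16],
            kernel_size=7, gru_hidden=16, seed=0))
        params = model.params()
        opt = AdamW(params, lr=3e-3)
        accuracy = 0.0
        for step in range(200):
            logits = model.forward(signals, train=True)
            loss, dlogits = cross_entropy(logits, targets)
            model.zero_grad()
            model.backward(dlogits)
            clip_grad_l2(params, 1.0)
            opt.step()
            accuracy = float(np.mean(np.argmax(logits, axis=1) == targets))
            if accuracy > 0.99:
                break
        assert accuracy > 0.99

    def test_empty_dataset_rejected(self):
        model = build_model(small_config())
        sampler = _ArrayBatchSampler(np.zeros((0, 1, 10)), np.zeros((0, 10), int))
        with pytest.raises(ValueError, match="empty"):
            train(model, sampler, None, TrainConfig(epochs=1))

    def test_training_deterministic(self, rng):
        signals, targets = _toy_problem(rng)
        losses = []
        for _ in range(2):
            model = build_model(small_config(seed=3))
            sampler = _ArrayBatchSampler(signals, targets)
            config = TrainConfig(epochs=2, batch_size=4, steps_per_epoch=3, seed=3)
            _, history = train(model, sampler, None, config)
            losses.append(history.epochs[-1]["train_loss"])
        assert losses[0] == losses[1]

    def test_history_csv(self, tmp_path, rng):
        signals, targets = _toy_problem(rng)
        model = build_model(small_config())
        sampler = _ArrayBatchSampler(signals, targets)
        _, history = train(model, sampler, None,
                           TrainConfig(epochs=2, batch_size=4, steps_per_epoch=2))
        out = tmp_path / "history.csv"
        history.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss,val_f1"
        assert len(lines) == 3


class TestSaveLoad:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        model = build_model(small_config(seed=9))
        x = rng.standard_normal(300)
        save_model(model, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        np.testing.assert_array_equal(infer(model, x), infer(loaded, x))

    def test_config_embedded(self, tmp_path):
        model = build_model(small_config(gru_hidden=16))
        save_model(model, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        assert loaded.config.gru_hidden == 16

    def test_not_a_checkpoint(self, tmp_path):
        np.savez(tmp_path / "junk.npz", a=np.zeros(3))
        with pytest.raises(ValueError, match="checkpoint"):
            load_model(tmp_path / "junk.npz")

    def test_mismatched_shapes_error(self, tmp_path):
        model = build_model(small_config())
        save_model(model, tmp_path / "model.npz")
        with np.load(tmp_path / "model.npz") as archive:
            state = {k: archive[k] for k in archive.files}
        other = build_model(small_config(gru_hidden=16))
        import json
        config_dict = json.loads(bytes(state["__config__"]).decode())
        state_no_cfg = {k: v for k, v in state.items() if k != "__config__"}
        with pytest.raises(ValueError, match="mismatch|missing"):
            other.load_state_dict(state_no_cfg)
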