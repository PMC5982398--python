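"""Fusion CNN building blocks: convolution, batch norm, pooling, forward pass."""

import numpy as np
import pytest

from emofusion import (
    ConvLayerSpec,
    FusionCNN,
    FusionModelConfig,
    aggregate_trial_prediction,
    batch_norm,
    conv2d,
    relu,
)
from emofusion.errors import ConfigurationError, InputError, ShapeError
from emofusion.fusion_model import BatchNormState, max_pool, max_pool_backward


class TestConv2d:
    def test_dimension_arithmetic_42x200(self, rng):
        """3x2 filter, stride (1, 2): 42x200 -> 40x100."""
        x = rng.standard_normal((1, 1, 42, 200))
        w = rng.standard_normal((4, 1, 3, 2))
        out, _ = conv2d(x, w, np.zeros(4), (1, 2))
        assert out.shape == (1, 4, 40, 100)

    def test_identity_1x1_filter(self, rng):
        x = rng.standard_normal((2, 1, 6, 7))
        w = np.ones((1, 1, 1, 1))
        out, _ = conv2d(x, w, np.zeros(1), (1, 1))
        assert np.allclose(out[:, 0], x[:, 0])

    def test_matches_hand_unrolled_dot_products(self, rng):
        x = rng.standard_normal((1, 2, 5, 5))
        w = rng.standard_normal((3, 2, 3, 2))
        b = rng.standard_normal(3)
        out, _ = conv2d(x, w, b, (1, 1))
        for f in range(3):
            for i in range(3):
                for j in range(4):
                    expect = (x[0, :, i : i + 3, j : j + 2] * w[f]).sum() + b[f]
                    assert out[0, f, i, j] == pytest.approx(expect, abs=1e-10)

    def test_input_smaller_than_filter_rejected(self, rng):
        with pytest.raises(ShapeError):
            conv2d(rng.standard_normal((1, 1, 2, 2)), rng.standard_normal((1, 1, 3, 2)), np.zeros(1), (1, 1))

    def test_default_conv_stack_geometry(self):
        """Frequency 42->40->38->36->34, time 200->100->50->25->12, pool -> 17x6."""
        cfg = FusionModelConfig.reference(n_classes=2)
        assert cfg.conv_output_shape() == (128, 17, 6)
        assert cfg.flat_dim == 128 * 17 * 6


class TestBatchNorm:
    def test_train_mode_standardizes(self, rng):
        x = rng.standard_normal((32, 6)) * 3 + 1
        st = BatchNormState(running_mean=np.zeros(6), running_var=np.ones(6))
        y, _ = batch_norm(x, st, np.ones(6), np.zeros(6), "train")
        assert np.all(np.abs(y.mean(axis=0)) < 1e-5)
        assert np.all(np.abs(y.var(axis=0) - 1) < 1e-3)

    def test_affine_law(self, rng):
        x = rng.standard_normal((64, 4))
        st = BatchNormState(running_mean=np.zeros(4), running_var=np.ones(4))
        y, _ = batch_norm(x, st, np.full(4, 2.0), np.full(4, 3.0), "train")
        assert np.allclose(y.mean(axis=0), 3.0, atol=1e-6)
        assert np.allclose(y.std(axis=0), 2.0, rtol=1e-3)

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal((16, 5))
        gamma, beta = rng.standard_normal(5), rng.standard_normal(5)
        st = BatchNormState(running_mean=np.zeros(5), running_var=np.ones(5), eps=1e-5)
        y, _ = batch_norm(x, st, gamma, beta, "train")
        mu, var = x.mean(axis=0), x.var(axis=0)
        expect = gamma * (x - mu) / np.sqrt(var + 1e-5) + beta
        assert np.allclose(y, expect, atol=1e-6)

    def test_infer_uses_running_stats(self, rng):
        x = rng.standard_normal((8, 3))
        st = BatchNormState(running_mean=np.full(3, 1.0), running_var=np.full(3, 4.0), initialized=True)
        y, _ = batch_norm(x, st, np.ones(3), np.zeros(3), "infer")
        assert np.allclose(y, (x - 1.0) / np.sqrt(4.0 + 1e-5), atol=1e-9)

    def test_batch_of_one_rejected_in_train(self, rng):
        st = BatchNormState(running_mean=np.zeros(3), running_var=np.ones(3))
        with pytest.raises(InputError):
            batch_norm(rng.standard_normal((1, 3)), st, np.ones(3), np.zeros(3), "train")


class TestRelu:
    @pytest.mark.parametrize("u,expect", [(-3.0, 0.0), (2.0, 2.0), (0.0, 0.0)])
    def test_branches(self, u, expect):
        assert relu(np.array(u)) == expect

    def test_idempotence(self, rng):
        x = rng.standard_normal((4, 5, 6))
        assert np.array_equal(relu(relu(x)), relu(x))


class TestMaxPool:
    def test_pool_and_backward_route_gradient_to_argmax(self, rng):
        x = rng.standard_normal((2, 3, 6, 8))
        out, cache = max_pool(x, (2, 2))
        assert out.shape == (2, 3, 3, 4)
        dout = np.ones_like(out)
        dx = max_pool_backward(dout, cache)
        assert dx.shape == x.shape
        assert dx.sum() == pytest.approx(out.size)
        # gradient lands only on the maxima
        assert np.all((dx != 0) <= (np.isclose(np.repeat(np.repeat(out, 2, 2), 2, 3), x)))


class TestForward:
    @pytest.fixture()
    def small_model(self):
        cfg = FusionModelConfig.reduced(2, gsr_dim=6, n_filters=(2, 3, 3, 3), fc_widths=(16, 12, 10, 8, 6, 4))
        return FusionCNN(cfg)

    def test_rows_are_probability_distributions(self, small_model, rng):
        params, state = small_model.init_params(rng)
        x = rng.standard_normal((32, 42, 200))
        g = rng.uniform(0, 2, 6)
        probs = small_model.forward(x, g, params, state, "infer")
        assert probs.shape == (32, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_distribution(self, small_model, rng):
        params, state = small_model.init_params(rng)
        params = {k: np.zeros_like(v) if k.endswith((".w", ".b", ".beta")) else v for k, v in params.items()}
        probs = small_model.forward(rng.standard_normal((4, 42, 200)), np.zeros(6), params, state, "infer")
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_infer_mode_bitwise_deterministic(self, small_model, rng):
        params, state = small_model.init_params(rng)
        x = rng.standard_normal((8, 42, 200))
        g = rng.uniform(0, 2, 6)
        a = small_model.forward(x, g, params, state, "infer")
        b = small_model.forward(x, g, params, state, "infer")
        assert np.array_equal(a, b)

    def test_wrong_gsr_length_raises_named_error(self, small_model, rng):
        params, state = small_model.init_params(rng)
        with pytest.raises(ShapeError, match="fusion"):
            small_model.forward(rng.standard_normal((2, 42, 200)), np.zeros(9), params, state)

    def test_wrong_image_shape_raises(self, small_model, rng):
        params, state = small_model.init_params(rng)
        with pytest.raises(ShapeError, match="input"):
            small_model.forward(rng.standard_normal((2, 40, 200)), np.zeros(6), params, state)


class TestConfigValidation:
    def test_reference_architecture_pins_layer_counts(self):
        cfg = FusionModelConfig.reference(4)
        cfg.validate(strict=True)
        assert len(cfg.conv_layers) == 4 and len(cfg.fc_sizes) == 7
        assert cfg.conv_layers[-1].batch_norm is False

    def test_strict_rejects_wrong_depth(self):
        cfg = FusionModelConfig(
            conv_layers=(ConvLayerSpec(4), ConvLayerSpec(4, batch_norm=False)),
            fc_sizes=(8, 2), n_classes=2, gsr_dim=4,
        )
        with pytest.raises(ConfigurationError):
            cfg.validate(strict=True)

    def test_fc_head_must_match_classes(self):
        with pytest.raises(ConfigurationError):
            FusionModelConfig(
                conv_layers=(ConvLayerSpec(4, batch_norm=False),),
                fc_sizes=(8, 3), n_classes=2, gsr_dim=4,
            )

    def test_filters_must_fit_input(self):
        with pytest.raises(ConfigurationError):
            FusionModelConfig(
                conv_layers=tuple(ConvLayerSpec(4, stride=(2, 2)) for _ in range(4)),
                fc_sizes=(8, 2), n_classes=2, gsr_dim=4, input_shape=(8, 8),
            )


class TestAggregate:
    def test_unanimous_rows(self):
        p = np.tile([0.0, 0.0, 1.0, 0.0], (32, 1))
        assert aggregate_trial_prediction(p) == 2

    def test_majority_with_symmetric_margins(self):
        p = np.vstack([np.tile([0.7, 0.3], (17, 1)), np.tile([0.3, 0.7], (15, 1))])
        assert aggregate_trial_prediction(p) == 0

    def test_uniform_rows_tie_to_lowest_index(self):
        assert aggregate_trial_prediction(np.full((32, 4), 0.25)) == 0

    def test_wrong_row_count_rejected(self):
        with pytest.raises(InputError):
            aggregate_trial_prediction(np.full((7, 2), 0.5))


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        from emofusion import load_checkpoint, save_checkpoint

        cfg = FusionModelConfig.reduced(4, gsr_dim=5)
        model = FusionCNN(cfg)
        params, state = model.init_params(rng)
        x = rng.standard_normal((4, 42, 200))
        model.loss_and_grads(x, np.zeros(5), np.eye(4), params, state)  # touch BN stats
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, cfg, params, state, extra={"scheme": "quadrant4"})
        cfg2, params2, state2, meta = load_checkpoint(p)
        assert cfg2 == cfg
        assert meta["scheme"] == "quadrant4"
        for k in params:
            assert np.array_equal(params[k], params2[k])
        for k in state:
            assert np.array_equal(state[k].running_mean, state2[k].running_mean)
        out1 = model.forward(x, np.zeros(5), params, state, "infer")
        out2 = FusionCNN(cfg2).forward(x, np.zeros(5), params2, state2, "infer")
        assert np.array_equal(out1, out2)
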