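"""Network architecture contracts and analytic-vs-numerical gradients."""

import numpy as np
import pytest

from virtstain import nn
from virtstain.cgan import (DiscriminatorConfig, GeneratorConfig,
                            PatchDiscriminator, UNetGenerator,
                            build_discriminator, build_generator)

RNG = np.random.default_rng(0)


def numerical_grad(f, x, idx, eps=1e-3):
    xp = x.copy()
    xp[idx] += eps
    xm = x.copy()
    xm[idx] -= eps
    return (f(xp) - f(xm)) / (2 * eps)


class TestGradients:
    """Analytic backward passes vs central differences (float32, so ~1e-3)."""

    @pytest.mark.parametrize("layer_factory", [
        lambda r: nn.Conv2d(2, 3, rng=r, init="gaussian"),
        lambda r: nn.ConvTranspose2d(2, 3, rng=r, init="gaussian"),
    ])
    def test_conv_layers_input_and_weight_grads(self, layer_factory):
        rng = np.random.default_rng(3)
        layer = layer_factory(rng)
        x = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        y = layer.forward(x, train=True)
        g = rng.standard_normal(y.shape).astype(np.float32)
        gx = layer.backward(g)

        def f(xv):
            return float((layer.forward(xv, train=False) * g).sum())

        for idx in [(0, 0, 2, 3), (0, 1, 7, 7), (0, 0, 0, 0)]:
            assert numerical_grad(f, x, idx) == pytest.approx(gx[idx], abs=2e-3)

        layer.zero_grads()
        layer.forward(x, train=True)
        layer.backward(g)
        W, gW = layer.W, layer.gW
        i = tuple(np.unravel_index(np.argmax(np.abs(gW)), gW.shape))
        w0 = W[i]
        W[i] = w0 + 1e-3
        lp = f(x)
        W[i] = w0 - 1e-3
        lm = f(x)
        W[i] = w0
        assert (lp - lm) / 2e-3 == pytest.approx(gW[i], abs=2e-3)

    def test_unet_end_to_end_gradient(self):
        cfg = GeneratorConfig(n_levels=3, base_channels=4, init="gaussian",
                              dropout_rate=0.0)
        gen = UNetGenerator(cfg, rng=np.random.default_rng(1))
        rng = np.random.default_rng(2)
        # 20x20 also exercises the reflect-pad/crop path (pads to 24)
        for size in (16, 20):
            x = rng.standard_normal((1, 3, size, size)).astype(np.float32)
            y = gen.forward(x, train=True)
            assert y.shape == x.shape
            g = rng.standard_normal(y.shape).astype(np.float32)
            gx = gen.backward(g)

            def f(xv):
                return float((gen.forward(xv, train=True) * g).sum())

            for idx in [(0, 0, 3, 4), (0, 2, size - 1, size - 1)]:
                assert numerical_grad(f, x, idx) == pytest.approx(gx[idx], abs=5e-3)

    def test_discriminator_input_gradient(self):
        disc = PatchDiscriminator(DiscriminatorConfig(base_channels=4, init="gaussian"),
                                  rng=np.random.default_rng(5))
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 6, 64, 64)).astype(np.float32)
        p = disc.forward(x, train=True)
        g = rng.standard_normal(p.shape).astype(np.float32)
        gin = disc.backward(g)
        assert gin.shape == x.shape

        def f(xv):
            return float((disc.forward(xv, train=True) * g).sum())

        for idx in [(0, 0, 5, 5), (0, 4, 33, 20)]:
            assert numerical_grad(f, x, idx) == pytest.approx(gin[idx], abs=1e-4)

    def test_batchnorm_gradient(self):
        bn = nn.BatchNorm2d(3)
        bn.gamma[:] = np.array([0.5, 1.5, 2.0])
        bn.beta[:] = np.array([0.1, -0.2, 0.0])
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        y = bn.forward(x, train=True)
        g = rng.standard_normal(y.shape).astype(np.float32)
        gx = bn.backward(g)

        def f(xv):
            return float((bn.forward(xv, train=True) * g).sum())

        for idx in [(0, 0, 2, 3), (0, 2, 5, 0)]:
            assert numerical_grad(f, x, idx) == pytest.approx(gx[idx], abs=5e-3)


class TestGeneratorContract:
    def test_output_shape_500_padded_path(self):
        gen = build_generator(seed=1)   # default: 8 levels
        x = RNG.standard_normal((1, 3, 500, 500)).astype(np.float32)
        y = gen.forward(x, train=False)
        assert y.shape == (1, 3, 500, 500)
        # padded to 512 internally: first encoder level is 256x256
        assert gen.last_encoder_shapes[0] == (256, 256)

    def test_output_shape_512_no_padding(self):
        gen = build_generator(seed=1)
        x = RNG.standard_normal((1, 3, 512, 512)).astype(np.float32)
        y = gen.forward(x, train=False)
        assert y.shape == (1, 3, 512, 512)
        assert gen._pad_layer.pad == ((0, 0), (0, 0))

    def test_bottleneck_spatial_size_is_2x2_for_512(self):
        gen = build_generator(seed=1)
        gen.forward(RNG.standard_normal((1, 3, 512, 512)).astype(np.float32),
                    train=False)
        assert gen.last_encoder_shapes[-1] == (2, 2)
        assert len(gen.last_encoder_shapes) == 8

    def test_output_range_within_tanh_bounds(self):
        gen = UNetGenerator(GeneratorConfig(n_levels=5, base_channels=8),
                            rng=np.random.default_rng(4))
        x = RNG.uniform(-1, 1, (1, 3, 64, 64)).astype(np.float32)
        y = gen.forward(x, train=False)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_default_config_echoes_architecture(self):
        cfg = GeneratorConfig()
        assert cfg.n_levels == 8
        assert cfg.kernel == 4 and cfg.stride == 2
        assert cfg.dropout_rate == 0.5
        assert cfg.channel_schedule() == [64, 128, 256, 512, 512, 512, 512, 512]

    def test_undersized_and_odd_inputs_rejected(self):
        gen = build_generator(seed=1)
        with pytest.raises(ValueError, match="minimum"):
            gen.forward(np.zeros((1, 3, 128, 128), dtype=np.float32))
        small = UNetGenerator(GeneratorConfig(n_levels=3, base_channels=4),
                              rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            small.forward(np.zeros((1, 3, 17, 17), dtype=np.float32))


class TestDiscriminatorContract:
    def test_outputs_strictly_in_unit_interval(self):
        disc = build_discriminator(seed=3)
        x = RNG.standard_normal((1, 6, 256, 256)).astype(np.float32)
        p = disc.forward(x, train=False)
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_512_input_gives_16x16_patch_map(self):
        disc = build_discriminator(seed=3)
        x = RNG.standard_normal((1, 6, 512, 512)).astype(np.float32)
        p = disc.forward(x, train=False)
        assert p.shape == (1, 1, 16, 16)

    def test_condition_and_candidate_are_not_symmetric(self):
        disc = build_discriminator(DiscriminatorConfig(base_channels=8), seed=9)
        rng = np.random.default_rng(10)
        a = rng.uniform(-1, 1, (1, 3, 64, 64)).astype(np.float32)
        b = rng.uniform(-1, 1, (1, 3, 64, 64)).astype(np.float32)
        p_ab = disc.forward(a, b, train=False)
        p_ba = disc.forward(b, a, train=False)
        assert not np.allclose(p_ab, p_ba)

    def test_mismatched_shapes_rejected(self):
        disc = build_discriminator(seed=3)
        with pytest.raises(ValueError, match="differ"):
            disc.forward(np.zeros((1, 3, 64, 64), dtype=np.float32),
                         np.zeros((1, 3, 64, 32), dtype=np.float32))

    def test_default_config_echoes_architecture(self):
        cfg = DiscriminatorConfig()
        assert cfg.n_down_blocks == 5
        assert cfg.final_channels == 1
        assert cfg.channel_schedule() == [64, 128, 256, 512, 512]


class TestInitialisation:
    def test_uniform_scheme_ranges(self):
        rng = np.random.default_rng(0)
        w = nn.init_weight(rng, (64, 3, 4, 4), "uniform")
        b = nn.init_bias(rng, (64,), "uniform")
        assert w.min() >= 0.0 and w.max() <= 0.02
        assert b.min() >= 0.0 and b.max() <= 0.01

    def test_gaussian_scheme_centered(self):
        rng = np.random.default_rng(0)
        w = nn.init_weight(rng, (256, 64, 4, 4), "gaussian")
        assert abs(float(w.mean())) < 1e-3
        assert float(w.std()) == pytest.approx(0.02, rel=0.05)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            nn.init_weight(np.random.default_rng(0), (2, 2), "xavier")
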