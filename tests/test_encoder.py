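import numpy as np
import pytest

import ssdfrn as s


# -- independent arithmetic oracle (no learned weights, no package shapes) ----

def _conv_len(n, k, stride):
    assert n >= k
    return (n - k) // stride + 1


def _oracle_mvccm(n, cfg):
    v1, v2, v3 = cfg.kernel_sizes
    total = 0
    detail = []
    for stride in cfg.strides:
        small = _conv_len(n, v1, stride)
        medium = _conv_len(small, v2, stride)
        big = _conv_len(small + medium, v3, stride)
        detail.append((small, medium, small + medium, big))
        total += big
    return total, detail


def _oracle_encoder(n, config):
    for mod in config.modules:
        if isinstance(mod, s.MVCCMConfig):
            n, _ = _oracle_mvccm(n, mod)
        else:
            n = _conv_len(n, mod.kernel_size, mod.stride)
        n = _conv_len(n, config.pool_window, config.pool_stride)
    return n


def _random_valid_config(rng):
    while True:
        v1 = int(rng.integers(2, 4))
        v2 = v1 + int(rng.integers(1, 3))
        v3 = v2 + 1
        strides = tuple(rng.permutation([1, 2, 3])[: 3])
        n_modules = int(rng.integers(1, 3))
        modules = tuple(
            s.MVCCMConfig(kernel_sizes=(v1, v2, v3), strides=strides, kernels=int(rng.integers(2, 6)))
            for _ in range(n_modules)
        )
        config = s.EncoderConfig(modules=modules, projection_width=int(rng.integers(4, 20)))
        length = int(rng.integers(16, 48))
        try:
            _oracle_encoder(length, config)
        except AssertionError:
            continue
        return config, length


class TestMVCCMShapes:
    def test_branch_lengths_for_default_module_on_length_18(self):
        total, detail = _oracle_mvccm(18, s.MVCCMConfig())
        assert [d[0] for d in detail] == [17, 9, 6]
        assert [d[1] for d in detail] == [15, 4, 2]
        assert [d[2] for d in detail] == [32, 13, 8]
        assert [d[3] for d in detail] == [29, 5, 2]
        assert total == 36
        built = s.mvccm_branch_lengths(18, s.MVCCMConfig())
        assert [b["big"] for b in built] == [29, 5, 2]

    def test_forward_output_matches_oracle(self, rng):
        cfg = s.MVCCMConfig(kernels=3)
        from ssdfrn.mvcnn_encoder import MVCCM

        block = MVCCM(1, cfg, rng)
        out = block.forward(rng.normal(size=(2, 1, 18)))
        assert out.shape == (2, 3, 36)

    def test_zero_weights_give_zero_output(self, rng):
        from ssdfrn.mvcnn_encoder import MVCCM

        block = MVCCM(1, s.MVCCMConfig(kernels=2), rng)
        for p in block.parameters():
            p.value[...] = 0.0
        out = block.forward(rng.normal(size=(3, 1, 18)))
        assert out.shape == (3, 2, 36)
        assert np.all(out == 0)


class TestEncoder:
    def test_default_encoder_flatten_width_and_projection(self, rng):
        enc = s.MVCNNEncoder(s.EncoderConfig(), 18, rng)
        assert enc.flatten_width == 576
        out = enc.forward(rng.normal(size=(4, 1, 18)))
        assert out.shape == (4, 18)

    def test_stage_lengths_match_oracle_over_random_configs(self, rng):
        for _ in range(30):
            config, length = _random_valid_config(rng)
            expected_final = _oracle_encoder(length, config)
            assert s.encoder_stage_lengths(length, config)[-1] == expected_final
            enc = s.MVCNNEncoder(config, length, rng)
            out = enc.forward(rng.normal(size=(2, 1, length)))
            assert out.shape == (2, config.projection_width)
            assert enc.flatten_width == expected_final * config.modules[-1].kernels

    def test_underflow_raises_config_error(self, rng):
        with pytest.raises(s.ShapeConfigError):
            s.MVCNNEncoder(s.EncoderConfig(), 6, rng)

    def test_forward_is_deterministic(self):
        x = np.random.default_rng(0).normal(size=(3, 1, 18))
        outs = []
        for _ in range(2):
            enc = s.MVCNNEncoder(s.EncoderConfig(), 18, np.random.default_rng(42))
            outs.append(enc.forward(x))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_zero_projection_gives_constant_output(self, rng):
        enc = s.MVCNNEncoder(s.EncoderConfig(), 18, rng)
        enc.projection.weight.value[...] = 0.0
        out = enc.forward(rng.normal(size=(5, 1, 18)))
        np.testing.assert_allclose(out, np.tile(enc.projection.bias.value, (5, 1)))

    def test_rebuild_for_new_length_shares_conv_params(self, rng):
        enc = s.MVCNNEncoder(s.EncoderConfig(), 18, rng)
        enc22 = enc.rebuild_for_length(22, rng)
        assert enc22.flatten_width == 768
        for p18, p22 in zip(enc.conv_parameters(), enc22.conv_parameters()):
            assert p18 is p22

    def test_kernel_permutation_equivariance(self, rng):
        # permuting first-module kernels plus matching downstream input
        # channels leaves the encoder output unchanged
        enc = s.MVCNNEncoder(
            s.EncoderConfig(modules=(s.MVCCMConfig(kernels=4), s.MVCCMConfig(kernels=3))),
            18,
            rng,
        )
        x = rng.normal(size=(2, 1, 18))
        baseline = enc.forward(x)
        perm = rng.permutation(4)
        for br in enc.blocks[0].branches:
            for name in ("small", "medium", "big"):
                br[name].weight.value = br[name].weight.value[perm]
                br[name].bias.value = br[name].bias.value[perm]
            for name in ("medium", "big"):
                br[name].weight.value = br[name].weight.value[:, perm]
        for br in enc.blocks[1].branches:
            br["small"].weight.value = br["small"].weight.value[:, perm]
        np.testing.assert_allclose(enc.forward(x), baseline, atol=1e-10)


class TestParameterCount:
    def test_single_conv_with_bias(self):
        config = s.EncoderConfig(
            modules=(s.PlainConvConfig(kernel_size=2, stride=1, kernels=1),),
            projection_width=1,
        )
        assert s.count_parameters(config) == 3  # 2 weights + 1 bias

    def test_conv_count_is_input_length_invariant_and_matches_built(self, rng):
        config = s.EncoderConfig()
        for length in (18, 22, 30):
            enc = s.MVCNNEncoder(config, length, rng)
            built = sum(p.value.size for p in enc.parameters())
            assert built == s.count_parameters(config, input_length=length)
        conv_only = s.count_parameters(config)
        assert conv_only == sum(
            p.value.size for p in s.MVCNNEncoder(config, 25, rng).conv_parameters()
        )

    def test_doubling_kernels_roughly_quadruples_module_two(self):
        base = s.EncoderConfig(modules=(s.MVCCMConfig(kernels=16), s.MVCCMConfig(kernels=32)))
        double = s.EncoderConfig(modules=(s.MVCCMConfig(kernels=16), s.MVCCMConfig(kernels=64)))
        m2_base = s.count_parameters(base) - s.count_parameters(
            s.EncoderConfig(modules=(s.MVCCMConfig(kernels=16),))
        )
        m2_double = s.count_parameters(double) - s.count_parameters(
            s.EncoderConfig(modules=(s.MVCCMConfig(kernels=16),))
        )
        assert 3.0 < m2_double / m2_base < 4.5
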