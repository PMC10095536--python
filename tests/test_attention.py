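"""CBAM attention gates and the U-net model contract."""

import numpy as np
import pytest

from leukoseg import nn
from leukoseg.attention_unet import (CBAM, ChannelAttention, ModelConfig,
                                     SpatialAttention, build_model, cbam,
                                     channel_attention, predict_mask,
                                     spatial_attention)


@pytest.fixture
def feature(rng):
    return rng.normal(size=(5, 6, 8))  # H x W x C


class TestChannelAttention:
    def test_shape_and_sigmoid_range(self, feature, rng):
        mod = ChannelAttention(8, reduction=4, rng=rng)
        gate = channel_attention(feature, mod)
        assert gate.shape == (1, 1, 8)
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_invariant_to_spatial_permutation(self, feature, rng):
        mod = ChannelAttention(8, reduction=4, rng=rng)
        h, w, c = feature.shape
        perm = np.random.default_rng(9).permutation(h * w)
        shuffled = feature.reshape(h * w, c)[perm].reshape(h, w, c)
        np.testing.assert_allclose(channel_attention(feature, mod),
                                   channel_attention(shuffled, mod), atol=1e-12)

    def test_matches_hand_computation_with_fixed_weights(self, rng):
        # 2 channels, bottleneck 1, hand-set weights
        mod = ChannelAttention(2, reduction=2, rng=rng)
        mod.fc1.weight.data = np.array([[1.0], [-1.0]])
        mod.fc1.bias.data = np.array([0.5])
        mod.fc2.weight.data = np.array([[2.0, -1.0]])
        mod.fc2.bias.data = np.array([0.1, -0.2])
        f = np.array([[[1.0, 4.0], [2.0, 0.0]],
                      [[3.0, 2.0], [-2.0, 6.0]]])  # (2, 2, 2) HWC
        avg = f.reshape(4, 2).mean(axis=0)
        mx = f.reshape(4, 2).max(axis=0)

        def mlp(v):
            hid = np.maximum(v @ np.array([[1.0], [-1.0]]) + 0.5, 0.0)
            return hid @ np.array([[2.0, -1.0]]) + np.array([0.1, -0.2])

        expected = 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))
        got = channel_attention(f, mod)[0, 0]
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestSpatialAttention:
    def test_shape_and_sigmoid_range(self, feature, rng):
        mod = SpatialAttention(7, rng)
        gate = spatial_attention(feature, mod)
        assert gate.shape == (5, 6, 1)
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_invariant_to_channel_permutation(self, feature, rng):
        mod = SpatialAttention(3, rng)
        perm = np.random.default_rng(9).permutation(feature.shape[2])
        np.testing.assert_allclose(spatial_attention(feature, mod),
                                   spatial_attention(feature[..., perm], mod),
                                   atol=1e-12)

    def test_impulse_kernel_hand_evaluation(self, rng):
        mod = SpatialAttention(3, rng)
        w = np.zeros((1, 2, 3, 3))
        w[0, 0, 1, 1] = 0.7   # weight on channel-mean map
        w[0, 1, 1, 1] = -0.3  # weight on channel-max map
        mod.conv.weight.data = w
        mod.conv.bias.data = np.array([0.2])
        f = rng.normal(size=(4, 4, 1))  # 1 channel: mean == max == f
        expected = 1.0 / (1.0 + np.exp(-(0.7 * f - 0.3 * f + 0.2)))
        np.testing.assert_allclose(spatial_attention(f, mod), expected, atol=1e-12)


class TestCBAM:
    def test_never_amplifies_and_preserves_shape(self, feature, rng):
        mod = CBAM(8, 4, 3, rng)
        out = cbam(feature, mod)
        assert out.shape == feature.shape
        assert np.all(np.abs(out) <= np.abs(feature) + 1e-15)

    def test_zero_input_gives_zero_output(self, rng):
        mod = CBAM(4, 2, 3, rng)
        np.testing.assert_array_equal(cbam(np.zeros((3, 3, 4)), mod), 0.0)

    def test_composes_channel_then_spatial(self, feature, rng):
        mod = CBAM(8, 4, 3, rng)
        y = feature * channel_attention(feature, mod.ca)
        expected = y * spatial_attention(y, mod.sa)
        np.testing.assert_allclose(cbam(feature, mod), expected, atol=1e-6)


class TestModel:
    def test_softmax_output_contract(self, rng):
        cfg = ModelConfig(num_classes=4, input_size=(64, 64), base_width=4)
        net = build_model(cfg, seed=0)
        x = rng.uniform(0, 1, (1, 3, 64, 64))
        with nn.no_grad():
            probs = net(x)
        assert probs.shape == (1, 4, 64, 64)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-5)
        assert probs.data.min() >= 0

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=(100, 100))

    def test_predict_mask_deterministic_with_valid_labels(self, rng):
        cfg = ModelConfig(num_classes=6, input_size=(32, 32), base_width=4)
        net = build_model(cfg, seed=3)
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        m1, m2 = predict_mask(net, img), predict_mask(net, img)
        np.testing.assert_array_equal(m1, m2)
        assert m1.shape == (32, 32)
        assert m1.min() >= 0 and m1.max() < 6

    def test_argmax_ties_break_to_lower_index(self):
        uniform = np.full((4, 4, 3), 1 / 3)
        assert np.argmax(uniform, axis=2).max() == 0  # documented tie rule

    def test_open_gates_reduce_to_plain_unet(self, rng):
        """Forcing every CBAM gate to ~1 reproduces a plain U-net forward."""
        cfg = ModelConfig(num_classes=3, input_size=(32, 32), base_width=4,
                          reduction_ratio=2, sam_kernel_size=3)
        net = build_model(cfg, seed=2)
        for mod in (net.cbam1, net.cbam2, net.cbam3, net.cbam4):
            mod.ca.fc1.weight.data[:] = 0.0
            mod.ca.fc1.bias.data[:] = 0.0
            mod.ca.fc2.weight.data[:] = 0.0
            mod.ca.fc2.bias.data[:] = 30.0  # sigmoid(60) ~ 1
            mod.sa.conv.weight.data[:] = 0.0
            mod.sa.conv.bias.data[:] = 30.0
        x = rng.uniform(0, 1, (1, 3, 32, 32))
        with nn.no_grad():
            gated = net(x).data
        for mod in (net.cbam1, net.cbam2, net.cbam3, net.cbam4):
            mod.forward = lambda t: t  # identity skip
        with nn.no_grad():
            plain = net(x).data
        np.testing.assert_allclose(gated, plain, atol=1e-6)
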