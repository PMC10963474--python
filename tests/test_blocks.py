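"""Building blocks: fire module arithmetic, ASPP branch structure and size
preservation, residual identity constructions, attention-gate analytics,
and exact parameter counting."""

import numpy as np
import pytest

from catseg import nn
from catseg.blocks import (ASPP, AttentionGate3D, FireModule, NetworkConfig,
                           ResidualBlock3D, count_parameters)
from catseg.nn import Conv, Tensor


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestFireModule:
    def test_output_channels_and_spatial_size(self, rng):
        fire = FireModule(8, 16, 64, 64, rng)
        y = fire(Tensor(rng.standard_normal((2, 8, 10, 12)).astype(np.float32)))
        assert y.shape == (2, 128, 10, 12)

    def test_zero_weights_give_zero_output(self, rng):
        fire = FireModule(4, 2, 3, 3, rng)
        _zero_params(fire)
        y = fire(Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32)))
        assert np.all(y.data == 0)

    def test_parameter_total_enumeration(self, rng):
        # 96->16 squeeze + 16->64 expand1x1 + 16->64 expand3x3, all biased:
        # 96*16+16 + 16*64+64 + 9*16*64+64 = 11,920
        fire = FireModule(96, 16, 64, 64, rng)
        assert count_parameters(fire) == 11920

    def test_channel_mismatch_rejected(self, rng):
        fire = FireModule(8, 2, 4, 4, rng)
        with pytest.raises(ValueError, match="expects 8 input channels, got 5"):
            fire(Tensor(np.zeros((1, 5, 6, 6), dtype=np.float32)))


class TestCountParameters:
    def test_ninefold_ratio_of_3x3_to_1x1(self, rng):
        c3 = Conv(16, 64, (3, 3), rng, bias=False)
        c1 = Conv(16, 64, (1, 1), rng, bias=False)
        assert count_parameters(c3) == 9 * count_parameters(c1)

    def test_1x1_conv_with_bias(self, rng):
        assert count_parameters(Conv(16, 64, (1, 1), rng)) == 16 * 64 + 64

    def test_matches_brute_force_enumeration(self, tiny_net_config):
        from catseg.localizer import build_localizer
        from catseg.segmenter import build_3daru
        for net in (build_localizer(tiny_net_config),
                    build_3daru(NetworkConfig(depth=3, base_channels=4, seed=0))):
            seen, total = set(), 0
            stack = [net]
            while stack:  # independent traversal of the object graph
                obj = stack.pop()
                if id(obj) in seen:
                    continue
                seen.add(id(obj))
                if isinstance(obj, nn.Parameter):
                    total += obj.data.size
                elif isinstance(obj, nn.Module):
                    stack.extend(vars(obj).values())
                elif isinstance(obj, (list, tuple)):
                    stack.extend(obj)
            assert count_parameters(net) == total


class TestASPP:
    def test_five_parallel_branches_for_three_rates(self, rng):
        aspp = ASPP(8, 16, (4, 8, 12), rng)
        assert aspp.n_branches == 5

    @pytest.mark.parametrize("size", [(16, 16), (13, 17)])
    def test_spatial_size_preserved(self, rng, size):
        aspp = ASPP(4, 8, (2, 4, 6), rng)
        y = aspp(Tensor(rng.standard_normal((1, 4) + size).astype(np.float32)))
        assert y.shape == (1, 8) + size

    def test_output_channels_equal_projection_width(self, rng):
        for rates in [(2,), (1, 2, 3, 4)]:
            aspp = ASPP(4, 6, rates, rng)
            y = aspp(Tensor(rng.standard_normal((1, 4, 9, 9)).astype(np.float32)))
            assert y.shape[1] == 6

    def test_input_smaller_than_largest_rate_rejected(self, rng):
        aspp = ASPP(4, 8, (2, 4, 6), rng)
        with pytest.raises(ValueError, match="dilation rate"):
            aspp(Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32)))


@pytest.mark.parametrize("rate", [4, 8, 12])
def test_dilated_conv_padding_rate_preserves_size(rng, rate):
    w = Tensor(rng.standard_normal((2, 3, 3, 3)))
    x = Tensor(rng.standard_normal((1, 3, 64, 64)))
    assert nn.conv(x, w, padding=rate, dilation=rate).shape == (1, 2, 64, 64)


class TestResidualBlock3D:
    def test_identity_under_zero_branch(self, rng):
        block = ResidualBlock3D(4, 4, rng)
        block.conv2.weight.data[...] = 0.0
        block.conv2.bias.data[...] = 0.0
        x = rng.standard_normal((1, 4, 6, 6, 4)).astype(np.float32)
        y = block(Tensor(x))
        np.testing.assert_allclose(y.data, x, rtol=1e-6)

    def test_output_shape_matches_input(self, rng):
        block = ResidualBlock3D(4, 4, rng)
        y = block(Tensor(rng.standard_normal((2, 4, 6, 6, 3)).astype(np.float32)))
        assert y.shape == (2, 4, 6, 6, 3)

    def test_strided_projection_shape(self, rng):
        block = ResidualBlock3D(4, 8, rng, stride=(2, 2, 1))
        y = block(Tensor(rng.standard_normal((1, 4, 8, 8, 3)).astype(np.float32)))
        assert y.shape == (1, 8, 4, 4, 3)

    def test_matches_manual_composition(self, rng):
        """Independently compose shortcut + branch step by step."""
        block = ResidualBlock3D(2, 2, rng)
        block.eval()
        x = Tensor(rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32))
        y = block(x)
        h = nn.batch_norm(x, block.bn1.gamma, block.bn1.beta,
                          block.bn1.running_mean, block.bn1.running_var, False)
        h = block.conv1(nn.relu(h))
        h = nn.batch_norm(h, block.bn2.gamma, block.bn2.beta,
                          block.bn2.running_mean, block.bn2.running_var, False)
        h = block.conv2(nn.relu(h))
        np.testing.assert_allclose(y.data, x.data + h.data, rtol=1e-5, atol=1e-6)


class TestAttentionGate:
    def _gate_inputs(self, rng, skip_ch=4, gate_ch=8, size=(8, 8, 3)):
        skip = Tensor(rng.standard_normal((1, skip_ch) + size).astype(np.float32))
        gate = Tensor(rng.standard_normal(
            (1, gate_ch, size[0] // 2, size[1] // 2, size[2])).astype(np.float32))
        return skip, gate

    def test_zero_weights_give_alpha_half(self, rng):
        gate_mod = AttentionGate3D(4, 8, rng)
        _zero_params(gate_mod)
        skip, gate = self._gate_inputs(rng)
        attended, alpha = gate_mod(skip, gate)
        np.testing.assert_allclose(alpha.data, 0.5, atol=1e-7)
        np.testing.assert_allclose(attended.data, 0.5 * skip.data, rtol=1e-6)

    def test_alpha_strictly_inside_unit_interval(self, rng):
        gate_mod = AttentionGate3D(4, 8, rng)
        skip, gate = self._gate_inputs(rng)
        _, alpha = gate_mod(skip, gate)
        assert np.all(alpha.data > 0) and np.all(alpha.data < 1)

    def test_saturated_bias_passes_skip_through(self, rng):
        gate_mod = AttentionGate3D(4, 8, rng)
        _zero_params(gate_mod)
        gate_mod.psi.bias.data[...] = 20.0
        skip, gate = self._gate_inputs(rng)
        attended, _ = gate_mod(skip, gate)
        assert np.abs(attended.data - skip.data).max() < 1e-6

    def test_non_halved_gate_rejected(self, rng):
        gate_mod = AttentionGate3D(4, 8, rng)
        skip = Tensor(np.zeros((1, 4, 8, 8, 3), dtype=np.float32))
        gate = Tensor(np.zeros((1, 8, 3, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="integer"):
            gate_mod(skip, gate)


class TestNetworkConfig:
    def test_rates_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            NetworkConfig(atrous_rates=(4, 4, 8))

    def test_depth_minimum(self):
        with pytest.raises(ValueError, match="depth"):
            NetworkConfig(depth=1)

    def test_default_rates_are_4_8_12(self):
        assert NetworkConfig().atrous_rates == (4, 8, 12)
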