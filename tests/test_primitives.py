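"""Unit tests for the perception operators: batch-norm arithmetic, SimAM,
coordinate attention, switchable atrous convolution, window tiling and the
windowed-attention stage."""

import numpy as np
import pytest

from ginsengdet import nn
from ginsengdet.nn.tensor import Tensor
from ginsengdet.primitives import (BNLayerState, CoordinateAttention, SimAM,
                                   SwinStage, SwinStageConfig,
                                   SwitchableAtrousConv, bn_forward,
                                   num_windows, window_partition,
                                   window_reverse)


def n_params(mod):
    return sum(p.size for p in mod.parameters())


# ---------------------------------------------------------------------------
# bn_forward
# ---------------------------------------------------------------------------

class TestBnForward:
    def test_hand_arithmetic(self):
        state = BNLayerState(gamma=[2.0], beta=[0.5], mean=[1.0],
                             std=[np.sqrt(3.99)], eps=0.01)
        y = bn_forward(np.full((1, 1, 2, 2), 3.0), state)
        assert np.allclose(y, 2.5)

    def test_input_at_mean_yields_beta(self, rng):
        state = BNLayerState(gamma=rng.normal(1, 0.5, 4),
                             beta=rng.normal(0, 1, 4),
                             mean=rng.normal(0, 1, 4),
                             std=rng.uniform(0.5, 2, 4))
        x = np.broadcast_to(state.mean.reshape(1, 4, 1, 1), (2, 4, 3, 3))
        assert np.allclose(bn_forward(x, state),
                           np.broadcast_to(state.beta.reshape(1, 4, 1, 1),
                                           (2, 4, 3, 3)))

    def test_zero_gamma_annihilates_input(self, rng):
        state = BNLayerState(gamma=np.zeros(3), beta=[1, 2, 3],
                             mean=np.zeros(3), std=np.ones(3))
        y = bn_forward(rng.normal(0, 5, (1, 3, 4, 4)), state)
        assert np.allclose(y, np.array([1, 2, 3]).reshape(1, 3, 1, 1))

    def test_channel_mismatch_and_bad_eps_raise(self):
        state = BNLayerState(np.ones(3), np.zeros(3), np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="channel"):
            bn_forward(np.zeros((1, 4, 2, 2)), state)
        with pytest.raises(ValueError, match="eps"):
            BNLayerState(np.ones(2), np.zeros(2), np.zeros(2), np.ones(2),
                         eps=0.0)


# ---------------------------------------------------------------------------
# SimAM
# ---------------------------------------------------------------------------

class TestSimAM:
    def test_zero_parameters(self):
        assert n_params(SimAM()) == 0

    def test_constant_channel_uniform_gate(self, rng):
        x = np.broadcast_to(rng.normal(0, 1, (1, 3, 1, 1)), (1, 3, 4, 4))
        y = SimAM()(Tensor(np.ascontiguousarray(x, dtype=np.float32))).data
        gate = y / np.where(x != 0, x, 1.0)
        for c in range(3):
            assert np.allclose(gate[0, c], gate[0, c].flat[0], atol=1e-6)

    def test_outlier_energy_hand_formula(self):
        lam = 1e-4
        x = np.array([1.0, 1.0, 1.0, 5.0])
        # independent evaluation of the energy weighting
        n = 3
        d = (x - x.mean()) ** 2
        v = d.sum() / n
        e_inv = d / (4 * (v + lam)) + 0.5
        expected = x * (1 / (1 + np.exp(-e_inv)))
        y = SimAM(lam)(Tensor(x.reshape(1, 1, 2, 2).astype(np.float32))).data
        assert np.allclose(y.reshape(-1), expected, rtol=1e-5)
        gate = y.reshape(-1) / x
        assert gate.argmax() == 3          # maximal at the outlier

    def test_single_pixel_guarded(self):
        y = SimAM()(Tensor(np.ones((1, 2, 1, 1), dtype=np.float32)))
        assert np.isfinite(y.data).all()


# ---------------------------------------------------------------------------
# Coordinate Attention
# ---------------------------------------------------------------------------

class TestCoordinateAttention:
    def test_shape_contract(self, rng):
        ca = CoordinateAttention(32, reduction=32)
        x = Tensor(rng.normal(0, 1, (2, 32, 5, 7)).astype(np.float32))
        assert ca(x).shape == (2, 32, 5, 7)

    def test_saturated_gates_identity(self, rng):
        ca = CoordinateAttention(16, reduction=32)
        ca.conv_h.bias.data[...] = 50.0
        ca.conv_w.bias.data[...] = 50.0
        ca.conv_h.weight.data[...] = 0.0
        ca.conv_w.weight.data[...] = 0.0
        ca.eval()
        x = Tensor(rng.normal(0, 1, (1, 16, 4, 6)).astype(np.float32))
        assert np.allclose(ca(x).data, x.data, atol=1e-5)

    def test_constant_input_constant_gates(self, rng):
        ca = CoordinateAttention(16)
        ca.eval()
        x = np.broadcast_to(rng.normal(0, 1, (1, 16, 1, 1)), (1, 16, 6, 6))
        y = ca(Tensor(np.ascontiguousarray(x, dtype=np.float32))).data
        assert np.allclose(y.std(axis=(2, 3)), 0.0, atol=1e-6)

    def test_parameter_count_closed_form(self):
        for c, red in [(64, 32), (256, 32), (512, 32), (64, 8)]:
            mid = max(8, c // red)
            expected = c * mid + 3 * mid + 2 * (mid * c + c)
            assert n_params(CoordinateAttention(c, red)) == expected

    def test_bad_reduction_raises(self):
        with pytest.raises(ValueError):
            CoordinateAttention(16, reduction=0)


# ---------------------------------------------------------------------------
# Switchable Atrous Convolution
# ---------------------------------------------------------------------------

class TestSAC:
    def test_equal_rates_warns(self):
        with pytest.warns(UserWarning, match="plain"):
            SwitchableAtrousConv(4, 4, rates=(2, 2))

    def test_shape_preserved_both_rates(self, rng):
        sac = SwitchableAtrousConv(8, 8, rates=(1, 3))
        x = Tensor(rng.normal(0, 1, (2, 8, 9, 11)).astype(np.float32))
        assert sac(x).shape == (2, 8, 9, 11)

    def test_switch_saturation_selects_rate1_branch(self, rng):
        from ginsengdet.nn import functional as F
        sac = SwitchableAtrousConv(4, 4)
        # silence the context modules and the weight delta
        for conv in (sac.pre_context, sac.post_context):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        sac.weight_diff.data[...] = 0.0
        sac.switch.weight.data[...] = 0.0
        sac.switch.bias.data[...] = 100.0          # S == 1 everywhere
        x = Tensor(rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32))
        w_hat = sac._standardised_weight()
        ref = F.conv2d(x, w_hat, stride=1, padding=1, dilation=1)
        assert np.allclose(sac(x).data, ref.data, atol=1e-5)

    def test_single_pixel_sees_center_tap_only(self, rng):
        sac = SwitchableAtrousConv(3, 3)
        for conv in (sac.pre_context, sac.post_context):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        sac.weight_diff.data[...] = 0.0
        x = rng.normal(0, 1, (1, 3, 1, 1)).astype(np.float32)
        y = sac(Tensor(x)).data
        w = sac._standardised_weight().data
        expected = (w[:, :, 1, 1] @ x[0, :, 0, 0]).reshape(1, 3, 1, 1)
        assert np.allclose(y, expected, atol=1e-5)

    def test_bad_rates_raise(self):
        with pytest.raises(ValueError):
            SwitchableAtrousConv(4, 4, rates=(0, 2))


# ---------------------------------------------------------------------------
# window tiling
# ---------------------------------------------------------------------------

class TestWindows:
    @pytest.mark.parametrize("H,W,ws,expected", [
        (4, 4, 4, 1),
        (32, 32, 4, 64),
        (7, 7, 7, 1),
        (20, 20, 7, 9),      # padding: ceil(20/7)^2
    ])
    def test_window_counts(self, H, W, ws, expected, rng):
        assert num_windows(H, W, ws) == expected
        x = Tensor(rng.normal(0, 1, (1, 3, H, W)).astype(np.float32))
        wins = window_partition(x, ws)
        assert wins.shape == (expected, ws, ws, 3)

    @pytest.mark.parametrize("H,W,ws", [(8, 8, 4), (10, 14, 4), (5, 9, 7)])
    def test_partition_reverse_bit_identical(self, H, W, ws, rng):
        x = Tensor(rng.normal(0, 1, (2, 5, H, W)).astype(np.float32))
        back = window_reverse(window_partition(x, ws), ws, H, W, 5)
        assert np.array_equal(back.data, x.data)

    def test_bad_window_size_raises(self):
        with pytest.raises(ValueError):
            window_partition(np.zeros((1, 1, 4, 4)), 0)


# ---------------------------------------------------------------------------
# Swin stage
# ---------------------------------------------------------------------------

class TestSwinStage:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="even"):
            SwinStageConfig(depth=3)
        with pytest.raises(ValueError, match="divisible"):
            SwinStageConfig(n_heads=5, embed_dim=64)
        cfg = SwinStageConfig(depth=2, n_heads=8, win_size=4, H=32, W=32)
        assert cfg.num_wins == 64

    @pytest.mark.parametrize("H,W,ws", [(8, 8, 4), (10, 10, 4), (7, 7, 7),
                                        (6, 6, 1)])
    def test_shape_preserved_even_with_padding(self, H, W, ws, rng):
        cfg = SwinStageConfig(depth=2, n_heads=4, win_size=ws, embed_dim=16)
        st = SwinStage(8, cfg)
        st.eval()
        x = Tensor(rng.normal(0, 1, (2, 8, H, W)).astype(np.float32))
        y = st(x)
        assert y.shape == (2, 16, H, W)
        assert np.isfinite(y.data).all()

    def test_relative_bias_parameter_law(self):
        for heads, ws in [(8, 4), (16, 4), (1, 7), (2, 1)]:
            cfg = SwinStageConfig(depth=2, n_heads=heads, win_size=ws,
                                  embed_dim=32)
            st = SwinStage(16, cfg)
            bias = sum(b.rel_bias.size for b in st.blocks)
            assert bias == 2 * heads * (2 * ws - 1) ** 2

    def test_block_parity_plain_then_shifted(self):
        st = SwinStage(8, SwinStageConfig(depth=4, n_heads=2, win_size=4,
                                          embed_dim=16))
        assert [b.shift for b in st.blocks] == [0, 2, 0, 2]

    def test_stage_gradients_flow(self, rng):
        cfg = SwinStageConfig(depth=2, n_heads=2, win_size=4, embed_dim=8)
        st = SwinStage(4, cfg)
        x = Tensor(rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32), True)
        y = st(x)
        y.sum().backward()
        assert x.grad is not None and np.isfinite(x.grad).all()
        for name, p in st.named_parameters():
            assert p.grad is not None, name
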