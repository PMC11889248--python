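"""Convolution decomposition, SEDD, MV2 and MobileViT block contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mnvit import nn
from mnvit.blocks import (BlockConfig, ConvSpec, DecomposedConv, MV2Block,
                          MobileViTBlock, SEDD, TransformerSpec,
                          conv_param_count, fold_patches, unfold_patches)
from mnvit.model_zoo import decomposition_savings
from mnvit.tensor import Tensor


def naive_two_stage_conv(x, dw, pw):
    """Direct-loop depthwise 3x3 ('same' padding) then pointwise 1x1."""
    c, h, w = x.shape
    mid = np.zeros_like(x)
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    for ci in range(c):
        for i in range(h):
            for j in range(w):
                mid[ci, i, j] = (xp[ci, i:i + 3, j:j + 3] * dw[ci]).sum()
    cout = pw.shape[0]
    out = np.zeros((cout, h, w))
    for o in range(cout):
        for ci in range(c):
            out[o] += pw[o, ci] * mid[ci]
    return out


class TestConvParamCount:
    def test_standard_form(self):
        assert conv_param_count(ConvSpec(3, 2, 4), decomposed=False) == 72

    def test_decomposed_vs_standard_at_48(self):
        assert conv_param_count(ConvSpec(3, 48, 48), decomposed=True) == 2736
        assert conv_param_count(ConvSpec(3, 48, 48), decomposed=False) == 20736

    def test_pointwise_degenerate(self):
        assert conv_param_count(ConvSpec(1, 5, 7), decomposed=True) == 5 + 35

    def test_bias_and_groups(self):
        assert conv_param_count(ConvSpec(3, 4, 4, groups=4, bias=True),
                                decomposed=False) == 9 * 4 + 4

    def test_stage_savings_sum_to_printed_delta(self):
        # the two 3x3 sites of each transformer stage, C in {48, 64, 80}
        assert decomposition_savings() == 302016

    def test_per_width_savings_closed_form(self):
        for c in (48, 64, 80):
            local = conv_param_count(ConvSpec(3, c, c), False) - \
                conv_param_count(ConvSpec(3, c, c), True)
            fusion = conv_param_count(ConvSpec(3, 2 * c, c), False) - \
                conv_param_count(ConvSpec(3, 2 * c, c), True)
            assert local == 8 * c * c - 9 * c
            assert fusion == 16 * c * c - 18 * c

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ConvSpec(2, 4, 4)
        with pytest.raises(ValueError):
            ConvSpec(3, 4, 6, groups=4)


class TestDecomposedConv:
    def test_matches_two_stage_loop_oracle(self, rng):
        conv = DecomposedConv(3, 5, norm_act=False)
        x = rng.normal(0, 1, (1, 3, 16, 16)).astype(np.float32)
        out = conv(Tensor(x)).data[0]
        ref = naive_two_stage_conv(x[0].astype(np.float64),
                                   conv.depthwise.weight.data.astype(np.float64),
                                   conv.pointwise.weight.data[:, :, 0, 0].astype(np.float64))
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_identity_factorization(self, rng):
        c = 4
        conv = DecomposedConv(c, c, norm_act=False)
        dw = np.zeros((c, 3, 3), dtype=np.float32)
        dw[:, 1, 1] = 1.0
        conv.depthwise.weight.data[...] = dw
        conv.pointwise.weight.data[...] = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
        x = rng.normal(0, 1, (2, c, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(conv(Tensor(x)).data, x, atol=1e-6)

    def test_weight_count_matches_closed_form(self):
        conv = DecomposedConv(48, 48)
        n_weights = conv.depthwise.weight.size + conv.pointwise.weight.size
        assert n_weights == conv_param_count(ConvSpec(3, 48, 48), decomposed=True)


class TestSEDD:
    def test_zeroed_se_halves_the_separable_stage(self, rng):
        sedd = SEDD(4, attention="se").eval()
        sedd.attention.fc1.weight.data[...] = 0
        sedd.attention.fc2.weight.data[...] = 0
        plain = SEDD(4, attention="none").eval()
        plain.depthwise.weight.data[...] = sedd.depthwise.weight.data
        x = rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(sedd(Tensor(x)).data, 0.5 * plain(Tensor(x)).data,
                                   atol=1e-6)

    def test_stride_halves_spatial_size(self, rng):
        sedd = SEDD(4, stride=2).eval()
        out = sedd(Tensor(rng.normal(0, 1, (1, 4, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 4, 16, 16)

    def test_composition_oracle(self, rng):
        sedd = SEDD(6, attention="se").eval()
        x = Tensor(rng.normal(0, 1, (1, 6, 5, 5)).astype(np.float32))
        staged = sedd.attention(sedd.act(sedd.norm(sedd.depthwise(x))))
        np.testing.assert_allclose(sedd(x).data, staged.data, atol=1e-6)


class TestMV2Block:
    def test_zero_projection_reduces_to_shortcut(self, rng):
        blk = MV2Block(BlockConfig(8, 8, stride=1)).eval()
        proj_conv = blk.project.layers[0]
        proj_conv.weight.data[...] = 0
        x = rng.normal(0, 1, (2, 8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-6)

    def test_stride_two_halves_and_drops_residual(self, rng):
        blk = MV2Block(BlockConfig(8, 16, stride=2)).eval()
        assert not blk.use_residual
        out = blk(Tensor(rng.normal(0, 1, (1, 8, 12, 12)).astype(np.float32)))
        assert out.shape == (1, 16, 6, 6)

    def test_se_branch_differs_only_by_channel_scaling(self, rng):
        se = SEDD(8, attention="se").eval()
        none = SEDD(8, attention="none").eval()
        none.depthwise.weight.data[...] = se.depthwise.weight.data
        x = Tensor(rng.normal(0, 1, (1, 8, 6, 6)).astype(np.float32))
        ratio = se(x).data / none(x).data
        per_channel = ratio.reshape(8, -1)
        # constant within each channel, strictly inside (0, 1)
        np.testing.assert_allclose(per_channel.std(axis=1), 0, atol=1e-6)
        means = per_channel.mean(axis=1)
        assert np.all(means > 0) and np.all(means < 1)

    def test_transformer_config_rejected(self):
        with pytest.raises(ValueError):
            MV2Block(BlockConfig(8, 8, transformer=TransformerSpec(16, 1)))


class TestUnfoldFold:
    def test_patch_counting(self, rng):
        seq = unfold_patches(rng.normal(0, 1, (3, 4, 4)), 2, 2)
        assert seq.shape == (4, 4, 3)

    def test_unit_patches_give_raster_scan(self, rng):
        x = rng.normal(0, 1, (2, 3, 4))
        seq = unfold_patches(x, 1, 1)
        np.testing.assert_array_equal(seq[:, 0, :],
                                      x.reshape(2, 12).T)

    def test_round_trip_identity(self, rng):
        x = rng.normal(0, 1, (5, 6, 8))
        back = fold_patches(unfold_patches(x, 2, 4), 6, 8, 2, 4)
        np.testing.assert_array_equal(back, x)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError):
            unfold_patches(np.zeros((1, 5, 4)), 2, 2)
        with pytest.raises(ValueError):
            fold_patches(np.zeros((4, 4, 1)), 5, 4, 2, 2)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(c=st.integers(1, 5), nh=st.integers(1, 4), nw=st.integers(1, 4),
           ph=st.integers(1, 4), pw=st.integers(1, 4), seed=st.integers(0, 2**16))
    def test_round_trip_and_conservation_property(self, c, nh, nw, ph, pw, seed):
        h, w = nh * ph, nw * pw
        x = np.random.default_rng(seed).normal(0, 1, (c, h, w))
        seq = unfold_patches(x, ph, pw)
        assert seq.size == x.size  # element conservation
        np.testing.assert_array_equal(fold_patches(seq, h, w, ph, pw), x)


def _mb_cfg(c=16, dim=24, depth=1, attention="none", decomposed=False):
    return BlockConfig(c, c, attention=attention, decomposed=decomposed,
                       transformer=TransformerSpec(dim=dim, depth=depth, heads=4))


class TestMobileViTBlock:
    @pytest.mark.parametrize("attention,decomposed", [
        ("none", False), ("se", False), ("nam", True), ("se", True)])
    def test_shape_preserved_and_finite(self, rng, attention, decomposed):
        blk = MobileViTBlock(_mb_cfg(attention=attention, decomposed=decomposed)).eval()
        x = rng.normal(0, 1, (2, 16, 8, 8)).astype(np.float32)
        out = blk(Tensor(x)).data
        assert out.shape == x.shape
        assert np.all(np.isfinite(out))

    def test_standard_structure_uses_plain_convs(self):
        blk = MobileViTBlock(_mb_cfg())
        assert isinstance(blk.local_conv, nn.ConvBNSiLU)
        assert isinstance(blk.fusion, nn.ConvBNSiLU)
        assert isinstance(blk.attention, nn.Identity)
        assert blk.local_conv.layers[0].kernel == 3
        assert blk.fusion.layers[0].in_channels == 32

    def test_decomposition_parameter_delta_at_48(self):
        from mnvit.model_zoo import count_parameters

        std = MobileViTBlock(_mb_cfg(c=48, dim=64, depth=2))
        dec = MobileViTBlock(_mb_cfg(c=48, dim=64, depth=2, decomposed=True))
        delta = count_parameters(std) - count_parameters(dec)
        assert delta == (8 * 48 ** 2 - 9 * 48) + (16 * 48 ** 2 - 18 * 48) == 54000

    def test_indivisible_map_resized_through_transformer(self, rng):
        blk = MobileViTBlock(_mb_cfg()).eval()
        x = rng.normal(0, 1, (1, 16, 7, 7)).astype(np.float32)
        out = blk(Tensor(x)).data
        assert out.shape == (1, 16, 7, 7)
        assert np.all(np.isfinite(out))

    def test_channel_change_rejected(self):
        with pytest.raises(ValueError):
            MobileViTBlock(BlockConfig(16, 24, transformer=TransformerSpec(24, 1)))
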