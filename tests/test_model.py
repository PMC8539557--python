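"""Architecture: distillation, attention, groups, upsampling, counts."""

import numpy as np
import pytest

from idman.model import (DFES, IDMAB, IDMAG, IDMAN, MAB, ChannelAttention,
                         DistillCascade, DistillStep, NetworkConfig,
                         TINY_CONFIG, Upsampler)

from _oracles import mab_oracle


def _zero_all(module):
    for _, p in module.named_parameters():
        p.value[...] = 0.0


class TestDistillation:
    def test_step_channel_split_counts(self):
        rng = np.random.default_rng(0)
        step = DistillStep(64, 16, rng, wn=False)
        x = rng.normal(size=(1, 64, 4, 4))
        distilled, coarse = step(x)
        assert distilled.shape == (1, 16, 4, 4)
        assert coarse.shape == (1, 48, 4, 4)

    def test_step_identity_survives_zero_conv(self):
        rng = np.random.default_rng(1)
        step = DistillStep(8, 2, rng, wn=False)
        step.refine.weight.value[...] = 0.0
        step.refine.bias.value[...] = 0.0
        x = rng.normal(size=(1, 8, 3, 3))
        _, coarse = step(x)
        np.testing.assert_allclose(coarse, np.maximum(x[:, 2:], 0.0))

    def test_step_zero_input_zero_output(self):
        step = DistillStep(8, 2, np.random.default_rng(2), wn=False)
        distilled, coarse = step(np.zeros((1, 8, 3, 3)))
        np.testing.assert_array_equal(distilled, 0.0)
        np.testing.assert_array_equal(coarse, 0.0)

    def test_step_requires_room_for_split(self):
        with pytest.raises(ValueError, match="in_channels > d"):
            DistillStep(4, 4, np.random.default_rng(0), wn=False)

    def test_cascade_channel_trace_64_16(self):
        """64 -> (16,48) -> (16,32) -> (16,16) -> conv 16; concat 64."""
        rng = np.random.default_rng(3)
        cascade = DistillCascade(64, 16, rng, wn=False)
        widths = [(s.retain.out_channels, s.refine.out_channels)
                  for s in cascade.steps]
        assert widths == [(16, 48), (16, 32), (16, 16)]
        assert cascade.last.out_channels == 16
        assert cascade.fuse.in_channels == 64
        assert cascade.fuse.out_channels == 64
        x = rng.normal(size=(1, 64, 4, 4))
        assert cascade(x).shape == (1, 64, 4, 4)

    def test_cascade_preserves_spatial_dims(self):
        rng = np.random.default_rng(4)
        cascade = DistillCascade(16, 4, rng, wn=True)
        for h, w in [(3, 5), (7, 2)]:
            assert cascade(rng.normal(size=(1, 16, h, w))).shape == (1, 16, h, w)

    def test_zero_cascade_maps_anything_to_zero(self):
        cascade = DistillCascade(16, 4, np.random.default_rng(5), wn=False)
        _zero_all(cascade)
        x = np.random.default_rng(6).normal(size=(2, 16, 4, 4))
        np.testing.assert_array_equal(cascade(x), 0.0)

    def test_cascade_matches_composed_steps(self):
        """The cascade equals its steps composed by hand."""
        rng = np.random.default_rng(7)
        cascade = DistillCascade(16, 4, rng, wn=False)
        x = rng.normal(size=(1, 16, 4, 4))
        parts = []
        cur = x
        for step in cascade.steps:
            d, cur = step(cur)
            parts.append(d)
        parts.append(cascade.last(cur))
        want = cascade.fuse(np.concatenate(parts, axis=1))
        np.testing.assert_allclose(cascade(x), want, atol=1e-12)


class TestAttention:
    def test_mab_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        mab = MAB(8, (3, 5), 2, rng, wn=False)
        x = rng.normal(size=(2, 8, 4, 4))
        branches = [{
            "pre_w": br.pre.weight.value, "pre_b": br.pre.bias.value,
            "down_w": br.down.weight.value, "down_b": br.down.bias.value,
            "up_w": br.up.weight.value, "up_b": br.up.bias.value,
            "post_w": br.post.weight.value, "post_b": br.post.bias.value,
        } for br in mab.branches]
        want = mab_oracle(x, branches, 2)
        assert np.max(np.abs(mab(x) - want)) < 1e-6

    def test_gate_bounded_and_contractive(self):
        rng = np.random.default_rng(9)
        mab = MAB(8, (3, 5), 2, rng, wn=False)
        x = rng.normal(size=(1, 8, 5, 5)) * 10
        y = mab(x)
        assert np.all(np.abs(y) <= np.abs(x))
        gates = y[np.abs(x) > 1e-9] / x[np.abs(x) > 1e-9]
        assert np.all(gates > 0.0) and np.all(gates < 1.0)

    def test_zero_input_gives_zero_output(self):
        rng = np.random.default_rng(10)
        mab = MAB(8, (3,), 2, rng, wn=False)
        np.testing.assert_array_equal(mab(np.zeros((1, 8, 3, 3))), 0.0)

    def test_channel_attention_equals_gate_neutral_mab(self):
        """With zero branch convs wired to pass-through, the MAB reduces
        to plain squeeze-and-excitation with matched weights."""
        rng = np.random.default_rng(11)
        ca = ChannelAttention(8, 2, rng, wn=False)
        mab = MAB(8, (3,), 2, np.random.default_rng(0), wn=False)
        br = mab.branches[0]
        # make pre/post convs identities (center tap 1)
        for conv in (br.pre, br.post):
            conv.weight.value[...] = 0.0
            conv.bias.value[...] = 0.0
            for c in range(8):
                conv.weight.value[c, c, 1, 1] = 1.0
        br.down.weight.value[...] = ca.down.weight.value
        br.down.bias.value[...] = ca.down.bias.value
        br.up.weight.value[...] = ca.up.weight.value
        br.up.bias.value[...] = ca.up.bias.value
        x = rng.normal(size=(2, 8, 4, 4))
        assert np.max(np.abs(ca(x) - mab(x))) < 1e-6

    def test_width_must_divide_reduction(self):
        with pytest.raises(ValueError, match="divisible"):
            ChannelAttention(6, 4, np.random.default_rng(0), wn=False)


class TestBlocksGroupsTrunk:
    def test_block_zero_residual_branch_is_identity(self):
        cfg = TINY_CONFIG
        block = IDMAB(cfg, np.random.default_rng(12))
        block.body.fuse.g.value[...] = 0.0  # WN gain zero -> zero weights
        block.body.fuse.bias.value[...] = 0.0
        x = np.random.default_rng(13).normal(size=(1, cfg.width, 6, 6))
        np.testing.assert_array_equal(block(x), x)

    def test_block_shape_preserved(self):
        block = IDMAB(TINY_CONFIG, np.random.default_rng(14))
        x = np.random.default_rng(15).normal(size=(2, 16, 3, 7))
        assert block(x).shape == x.shape

    def test_plain_conv_block_matches_manual_composition(self):
        """Distillation off + channel attention: the block must equal an
        independently composed residual attention block."""
        cfg = NetworkConfig(scale=2, n_groups=1, n_blocks=1, width=8,
                            distill_channels=2, mab_branch_kernels=(),
                            reduction_ratio=2, use_distillation=False,
                            use_weight_norm=False)
        block = IDMAB(cfg, np.random.default_rng(16))
        x = np.random.default_rng(17).normal(size=(1, 8, 4, 4))
        body = block.body.conv2(np.maximum(block.body.conv1(x), 0.0))
        z = body.mean(axis=(2, 3), keepdims=True)
        e = block.attention.up(np.maximum(block.attention.down(z), 0.0))
        gate = 1.0 / (1.0 + np.exp(-e))
        want = x + gate * body
        assert np.max(np.abs(block(x) - want)) < 1e-6

    def test_group_zero_trailing_conv_is_identity(self):
        group = IDMAG(TINY_CONFIG, np.random.default_rng(18))
        group.conv.v.value[...] = 0.0  # direction zeroed -> guard
        group.conv.g.value[...] = 0.0
        group.conv.v.value[:, 0, 0, 0] = 1.0  # restore nonzero direction
        group.conv.bias.value[...] = 0.0
        x = np.random.default_rng(19).normal(size=(1, 16, 5, 5))
        np.testing.assert_array_equal(group(x), x)

    def test_group_matches_manual_composition(self):
        group = IDMAG(TINY_CONFIG, np.random.default_rng(20))
        x = np.random.default_rng(21).normal(size=(1, 16, 4, 4))
        cur = x
        for block in group.blocks:
            cur = block(cur)
        want = x + group.conv(cur)
        np.testing.assert_allclose(group(x), want, atol=1e-12)

    def test_trunk_matches_manual_composition(self):
        trunk = DFES(TINY_CONFIG, np.random.default_rng(22))
        x = np.random.default_rng(23).normal(size=(1, 16, 4, 4))
        cur = x
        for group in trunk.groups:
            cur = group(cur)
        want = x + trunk.conv(cur)
        np.testing.assert_allclose(trunk(x), want, atol=1e-12)
        assert trunk(x).shape[1] == 16

    def test_trunk_finite_for_random_params(self):
        trunk = DFES(TINY_CONFIG, np.random.default_rng(24))
        x = np.random.default_rng(25).normal(size=(1, 16, 8, 8))
        assert np.all(np.isfinite(trunk(x)))


class TestUpsamplerAndNetwork:
    @pytest.mark.parametrize("scale,expected", [(2, (1, 4, 16, 16)),
                                                (3, (1, 4, 24, 24)),
                                                (4, (1, 4, 32, 32))])
    def test_upsampler_shapes(self, scale, expected):
        up = Upsampler(4, scale, np.random.default_rng(26))
        x = np.random.default_rng(27).normal(size=(1, 4, 8, 8))
        assert up(x).shape == expected

    def test_upsampler_x4_is_two_x2_stages(self):
        up = Upsampler(4, 4, np.random.default_rng(28))
        assert len(up.convs) == 2
        assert all(s.scale == 2 for s in up.shuffles)

    def test_unsupported_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            Upsampler(4, 5, np.random.default_rng(0))

    def test_network_output_shape(self, tiny_model):
        x = np.random.default_rng(29).random((1, 1, 24, 24))
        assert tiny_model.forward(x).shape == (1, 1, 48, 48)

    def test_forward_is_deterministic(self, tiny_model):
        x = np.random.default_rng(30).random((1, 1, 12, 12))
        a = tiny_model.forward(x)
        b = tiny_model.forward(x)
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_closed_form(self, tiny_model):
        """Analytic parameter count for the tiny config, layer by layer."""
        def conv_n(cin, cout, k, wn):
            # weight/direction + bias, plus a per-channel gain under WN
            return cin * cout * k * k + cout + (cout if wn else 0)

        C, d, r = 16, 4, 4
        cascade = (
            sum(conv_n(d, d, 1, True) +  # retained 1x1
                conv_n(C - (i + 1) * d, C - (i + 1) * d, 3, True)
                for i in range(3))
            + conv_n(C - 3 * d, d, 3, True)   # final distilled conv
            + conv_n(4 * d, C, 1, True))      # fusion
        branch = lambda k: (conv_n(C, C, k, True) + conv_n(C, C // r, 1, True)
                            + conv_n(C // r, C, 1, True) + conv_n(C, C, k, True))
        block = cascade + branch(3) + branch(5)
        group = 2 * block + conv_n(C, C, 3, True)
        trunk = 2 * group + conv_n(C, C, 3, True)
        total = (conv_n(1, C, 3, False) + trunk
                 + conv_n(C, C * 4, 3, False)   # x2 sub-pixel stage
                 + conv_n(C, 1, 3, False))
        assert tiny_model.n_parameters() == total

    def test_gradient_reaches_every_parameter(self):
        """A single backward pass leaves no dead parameter group."""
        model = IDMAN(TINY_CONFIG, rng=31)
        rng = np.random.default_rng(32)
        x = rng.random((1, 1, 8, 8))
        y = model.forward(x)
        model.zero_grad()
        model.backward(np.sign(y - rng.random(y.shape)))
        for name, p in model.named_parameters():
            assert np.any(p.grad != 0.0), f"dead parameter group: {name}"

    def test_config_validation(self):
        with pytest.raises(ValueError, match="3\\*"):
            NetworkConfig(width=12, distill_channels=4,
                          reduction_ratio=4).validate()
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig(width=16, distill_channels=4, reduction_ratio=4,
                          mab_branch_kernels=(4,)).validate()
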