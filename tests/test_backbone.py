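"""Multi-path dilated residual blocks, presets, and coverage analysis."""

import numpy as np
import pytest

from nucseg import backbone as B
from nucseg.autodiff import Tensor
from nucseg.nn import conv2d
from nucseg.norm import NormSpec, make_norm


class TestSpecs:
    def test_dilated_conv_spec_validation(self):
        with pytest.raises(ValueError):
            B.DilatedConvSpec(kernel=4)
        with pytest.raises(ValueError):
            B.DilatedConvSpec(rate=0)

    def test_block_spec_requires_rate_one(self):
        with pytest.raises(ValueError):
            B.MultiPathBlockSpec(8, 4, 8, rates=(2, 5))

    def test_identity_shortcut_channel_mismatch(self):
        with pytest.raises(B.ConfigurationError):
            B.MultiPathBlockSpec(8, 4, 16, shortcut="identity")

    def test_channel_cap_enforced(self):
        with pytest.raises(B.ConfigurationError):
            B.BackboneConfig(stages=(B.StageSpec(1, 512, 64),))

    def test_declared_depth_checked(self):
        with pytest.raises(B.ConfigurationError):
            B.BackboneConfig(stages=(B.StageSpec(1, 64, 16),), declared_depth=10)


class TestMultiPathBlock:
    def test_stride1_preserves_spatial_size(self, rng):
        spec = B.MultiPathBlockSpec(8, 4, 8, normalization=NormSpec(num_groups=4))
        block = B.build_block(spec, rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 32, 32)))
        assert block(x).shape == (1, 8, 32, 32)

    def test_zero_weights_pure_shortcut(self, rng):
        spec = B.MultiPathBlockSpec(8, 4, 8, normalization=NormSpec(num_groups=4))
        block = B.build_block(spec, rng=rng)
        for _, p in block.named_parameters():
            p.data[...] = 0.0
        x_data = np.abs(rng.normal(size=(1, 8, 16, 16)))   # post-ReLU regime
        out = block(Tensor(x_data))
        np.testing.assert_allclose(out.data, x_data, atol=1e-12)

    def test_single_rate_sum_merge_equals_plain_bottleneck(self, rng):
        """Rates (1,) with sum merge is weight-for-weight a plain bottleneck."""
        norm = NormSpec(num_groups=4)
        spec = B.MultiPathBlockSpec(8, 4, 8, rates=(1,), merge="sum",
                                    normalization=norm)
        block = B.build_block(spec, rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 12, 12)))
        got = block(x)

        def norm_apply(w_layer, t):
            return w_layer(t)
        reduce_n = make_norm(4, norm)
        path_n = make_norm(4, norm)
        restore_n = make_norm(8, norm)
        for dst, src in ((reduce_n, block.reduce_norm), (path_n, block.path_norms[0]),
                         (restore_n, block.restore_norm)):
            dst.load_state_dict(src.state_dict())
        h = norm_apply(reduce_n, conv2d(x, block.reduce.weight, None)).relu()
        h = norm_apply(path_n, conv2d(h, block.paths[0].weight, None, padding=1)).relu()
        h = norm_apply(restore_n, conv2d(h, block.restore.weight, None))
        want = (h + x).relu()
        assert np.abs(got.data - want.data).max() < 1e-5

    def test_projection_shortcut_when_channels_change(self, rng):
        spec = B.MultiPathBlockSpec(8, 4, 16, normalization=NormSpec(num_groups=4))
        block = B.build_block(spec, rng=rng)
        assert block.proj is not None
        out = block(Tensor(rng.normal(size=(1, 8, 8, 8))))
        assert out.shape == (1, 16, 8, 8)


class TestBackbonePresets:
    def test_depth_counts(self):
        assert B.count_weight_layers(B.dresnet64_config()) == 64
        assert B.count_weight_layers(B.dresnet16_config()) == 16

    def test_resnet50_shaped_count(self):
        """The classical (3, 4, 6, 3) bottleneck layout counts 49 convolutions."""
        cfg = B.BackboneConfig(stages=(
            B.StageSpec(3, 64, 16), B.StageSpec(4, 128, 32),
            B.StageSpec(6, 256, 64), B.StageSpec(3, 256, 64)))
        assert B.count_weight_layers(cfg) == 49

    def test_empty_config_counts_zero(self):
        assert B.count_weight_layers(B.BackboneConfig()) == 0

    def test_single_block_counts_three(self):
        """One block alone: 1x1 reduce + parallel stage (counted once) + 1x1."""
        cfg = B.BackboneConfig(stem_channels=0, stages=(B.StageSpec(1, 64, 16),))
        assert B.count_weight_layers(cfg) == 3

    def test_channel_cap_in_built_preset(self, rng):
        net = B.build_backbone(B.dresnet16_config(), rng=rng)
        for name, p in net.named_parameters():
            if p.data.ndim == 4:            # convolution weights
                assert p.data.shape[0] <= 256, name

    def test_dilated_stages_share_spatial_size(self, rng):
        """Late stages trade striding for dilation: sizes stop shrinking."""
        cfg = B.dresnet16_config()          # same stride plan as the deep preset
        net = B.build_backbone(cfg, rng=rng)
        outs = net(Tensor(rng.normal(size=(1, 3, 64, 64))))
        sizes = [v.shape[2:] for v in outs.values()]
        assert sizes[0] == (16, 16)         # stride 4 after the stem
        assert sizes[1] == sizes[2] == sizes[3] == (8, 8)

    def test_backbone_requires_stages(self):
        with pytest.raises(B.ConfigurationError):
            B.build_backbone(B.BackboneConfig())


class TestReceptiveField:
    def test_closed_form_examples(self):
        assert B.receptive_field([B.DilatedConvSpec(rate=1)]) == 3
        assert B.receptive_field([B.DilatedConvSpec(rate=2)]) == 5
        assert B.receptive_field([B.DilatedConvSpec()] * 3) == 7

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            B.receptive_field([])

    @pytest.mark.parametrize("rates", [(1,), (2,), (1, 2), (2, 2, 2), (1, 2, 5),
                                       (5, 2, 1), (3, 3, 3, 3)])
    def test_matches_influence_oracle(self, rates, rng):
        """Closed form equals the support of the gradient influence map of a
        unit-weight convolution stack (brute-force oracle)."""
        stack = [B.DilatedConvSpec(rate=r) for r in rates]
        extent = B.receptive_field(stack)
        grid = extent + 4
        x = Tensor(rng.normal(size=(1, 1, grid, grid)), requires_grad=True)
        h = x
        for s in stack:
            w = Tensor(np.ones((1, 1, 3, 3)))
            h = conv2d(h, w, None, dilation=s.rate, padding=s.rate)
        center = grid // 2
        h[0, 0, center, center].backward()
        ys, xs = np.nonzero(x.grad[0, 0])
        assert ys.max() - ys.min() + 1 == extent
        assert xs.max() - xs.min() + 1 == extent


class TestCoverage:
    def test_single_rate1_full_neighborhood(self):
        cov = B.coverage_map([B.DilatedConvSpec(rate=1)], 5)
        c = 5 // 2
        assert (cov[c - 1:c + 2, c - 1:c + 2] == 1).all()
        assert cov.sum() == 9

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError):
            B.coverage_map([B.DilatedConvSpec(rate=2)], 3)

    def test_stacked_rate2_has_gridding_holes(self):
        """Three stacked rate-2 convolutions skip the odd-offset positions."""
        stack = [B.DilatedConvSpec(rate=2)] * 3
        extent = B.receptive_field(stack)            # 13
        cov = B.coverage_map(stack, extent)
        c = extent // 2
        inside = cov
        # odd offsets from the center never contribute
        for dy in range(-6, 7):
            for dx in range(-6, 7):
                if dy % 2 or dx % 2:
                    assert inside[c + dy, c + dx] == 0
                else:
                    assert inside[c + dy, c + dx] > 0

    def test_coverage_equals_gradient_influence_counts(self, rng):
        """Offset-chain enumeration equals the unit-weight gradient map."""
        stack = [B.DilatedConvSpec(rate=2)] * 3
        grid = 17
        cov = B.coverage_map(stack, grid)
        x = Tensor(rng.normal(size=(1, 1, grid, grid)), requires_grad=True)
        h = x
        for s in stack:
            h = conv2d(h, Tensor(np.ones((1, 1, 3, 3))), None,
                       dilation=s.rate, padding=s.rate)
        h[0, 0, grid // 2, grid // 2].backward()
        np.testing.assert_array_equal(cov, x.grad[0, 0].astype(np.int64))

    def test_multipath_block_covers_union_receptive_field(self):
        """Every position inside the union of the parallel paths' fields
        contributes — no gridding holes in the merged block."""
        rates = (1, 2, 5)
        cov = B.multipath_coverage_map(rates, grid_size=11)
        c = 11 // 2
        union = np.zeros_like(cov, dtype=bool)
        for r in rates:
            for dy in (-r, 0, r):
                for dx in (-r, 0, r):
                    union[c + dy, c + dx] = True
        assert (cov[union] > 0).all()
        assert (cov[~union] == 0).all()
        assert cov[c, c] == len(rates) + 1          # all paths + shortcut
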