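"""Coordinate transform, upsampling, pyramid shape contract, fusion algebra,
and an analytic parameter-count oracle for the residual backbone."""

import numpy as np
import pytest

from ccanet.backbone import (BLOCK_PLANS, EXPANSION, BackboneConfig,
                             ResidualBackbone)
from ccanet.fpn import (FeaturePyramidFusion, nn_coord, resize_nearest,
                        upsample_nearest_2x)
from ccanet.nn import Tensor


class TestNNCoord:
    def test_identity_when_sizes_equal(self):
        for x, y in [(0, 0), (3, 5), (7, 7)]:
            assert nn_coord(x, y, 8, 8, 8, 8) == (x, y)

    def test_halving_floors(self):
        # dstX=3 with srcW=2, dstW=4: 3 * 0.5 = 1.5 -> index 1
        assert nn_coord(3, 0, 2, 1, 4, 1)[0] == 1

    def test_index_always_within_source(self):
        # in-range destination pixels always land inside the source grid
        for dst_w, src_w in ((5, 10), (3, 1), (4, 2), (7, 7)):
            for dx in range(dst_w):
                sx, _ = nn_coord(dx, 0, src_w, 1, dst_w, 1)
                assert 0 <= sx < src_w
        assert nn_coord(4, 0, 10, 1, 5, 1)[0] == 8

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nn_coord(5, 0, 4, 4, 5, 4)
        with pytest.raises(ValueError):
            nn_coord(-1, 0, 4, 4, 4, 4)

    def test_resize_nearest_consistent_with_nn_coord(self, rng):
        img = rng.normal(size=(3, 5, 7))
        out = resize_nearest(img, 9, 4)
        for dy in range(9):
            for dx in range(4):
                sx, sy = nn_coord(dx, dy, 7, 5, 4, 9)
                np.testing.assert_array_equal(out[:, dy, dx], img[:, sy, sx])


class TestUpsample2x:
    def test_single_pixel_replicates(self):
        x = np.full((1, 1, 1, 1), 7.0)
        np.testing.assert_array_equal(upsample_nearest_2x(x),
                                      np.full((1, 1, 2, 2), 7.0))

    def test_known_2x2_pattern(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        expected = np.array([[1, 1, 2, 2], [1, 1, 2, 2],
                             [3, 3, 4, 4], [3, 3, 4, 4]], dtype=float)
        np.testing.assert_array_equal(upsample_nearest_2x(x)[0, 0], expected)

    def test_sum_conservation(self, rng):
        x = rng.normal(size=(2, 3, 4, 5))
        assert upsample_nearest_2x(x).sum() == pytest.approx(4 * x.sum())

    def test_matches_per_pixel_nn_coord_exhaustively(self, rng):
        for h in range(1, 9):
            for w in range(1, 9):
                x = rng.normal(size=(1, 1, h, w))
                up = upsample_nearest_2x(x)
                for dy in range(2 * h):
                    for dx in range(2 * w):
                        sx, sy = nn_coord(dx, dy, w, h, 2 * w, 2 * h)
                        assert up[0, 0, dy, dx] == x[0, 0, sy, sx]


def analytic_backbone_params(cfg: BackboneConfig) -> int:
    """Closed-form conv + batch-norm parameter count of the backbone."""
    total = 3 * cfg.stem_channels * 49 + 2 * cfg.stem_channels
    in_ch = cfg.stem_channels
    for n_blocks, inner in zip(cfg.blocks, cfg.inner_widths):
        out_ch = inner * EXPANSION
        for b in range(n_blocks):
            total += in_ch * inner + 2 * inner            # 1x1 reduce + bn
            total += inner * inner * 9 + 2 * inner        # 3x3 + bn
            total += inner * out_ch + 2 * out_ch          # 1x1 expand + bn
            if b == 0:                                    # projection skip
                total += in_ch * out_ch + 2 * out_ch
            in_ch = out_ch
    return total


class TestBackbone:
    @pytest.mark.parametrize("depth", [50, 101])
    def test_parameter_count_matches_analytic_oracle(self, depth):
        cfg = BackboneConfig.tiny(depth)
        bb = ResidualBackbone(cfg)
        assert bb.n_parameters() == analytic_backbone_params(cfg)

    def test_standard_width_depth50_count(self):
        # full-width plan: the classic 50-layer residual trunk
        cfg = BackboneConfig(depth=50)
        bb = ResidualBackbone(cfg)
        assert bb.n_parameters() == analytic_backbone_params(cfg)

    def test_deeper_plan_has_more_parameters(self):
        assert (ResidualBackbone(BackboneConfig.tiny(101)).n_parameters()
                > ResidualBackbone(BackboneConfig.tiny(50)).n_parameters())

    def test_level_shapes_for_128_input(self, rng):
        bb = ResidualBackbone(BackboneConfig.tiny())
        c = bb(Tensor(rng.normal(size=(2, 3, 128, 128)).astype(np.float32)))
        widths = BackboneConfig.tiny().out_channels
        for (name, stride), w in zip(
                [("c2", 4), ("c3", 8), ("c4", 16), ("c5", 32)], widths):
            assert c[name].shape == (2, w, 128 // stride, 128 // stride)

    def test_indivisible_input_rejected(self, rng):
        bb = ResidualBackbone(BackboneConfig.tiny())
        with pytest.raises(ValueError, match="divisible by 32"):
            bb(Tensor(rng.normal(size=(1, 3, 100, 100)).astype(np.float32)))

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(depth=34)

    def test_zero_input_finite_output(self):
        bb = ResidualBackbone(BackboneConfig.tiny())
        bb.eval()
        c = bb(Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32)))
        for v in c.values():
            assert np.isfinite(v.data).all()


def tiny_levels(rng, batch=2, base=32):
    widths = BackboneConfig.tiny().out_channels
    return {f"c{i+2}": Tensor(rng.normal(
        size=(batch, w, base >> i, base >> i)).astype(np.float32))
        for i, w in enumerate(widths)}


class TestFusion:
    def test_p_level_shape_contract(self, rng):
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=256)
        p = fpn.topdown_fuse(tiny_levels(rng))
        for i, size in zip((2, 3, 4, 5), (32, 16, 8, 4)):
            assert p[f"p{i}"].shape == (2, 256, size, size)
        fused = fpn.smooth_and_splice(p)
        assert fused.shape == (2, 1024, 32, 32)

    def test_zero_lateral_kernels_give_zero_pyramid(self, rng):
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=8)
        for conv in fpn.lateral:
            conv.weight.data[...] = 0
            conv.bias.data[...] = 0
        p = fpn.topdown_fuse(tiny_levels(rng))
        for v in p.values():
            np.testing.assert_array_equal(v.data, 0)

    def test_fusion_linear_with_zero_biases(self, rng):
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=8)
        for conv in fpn.lateral:
            conv.bias.data[...] = 0
        c1 = tiny_levels(rng)
        p1 = fpn.topdown_fuse(c1)
        c2 = {k: Tensor(3.0 * v.data) for k, v in c1.items()}
        p2 = fpn.topdown_fuse(c2)
        for k in p1:
            np.testing.assert_allclose(p2[k].data, 3.0 * p1[k].data,
                                       rtol=1e-4, atol=1e-5)

    def test_single_pixel_c5_replication_oracle(self, rng):
        # one-pixel top level: after lateral conv, p5's value must replicate
        # into a 2x2 block inside p4
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=4)
        levels = tiny_levels(rng, batch=1, base=8)   # c5 is 1x1
        p = fpn.topdown_fuse(levels)
        lat4 = fpn.lateral_project(levels["c4"], 4)
        manual_p4 = lat4.data + p["p5"].data.repeat(2, axis=2).repeat(2, axis=3)
        np.testing.assert_allclose(p["p4"].data, manual_p4, atol=1e-6)

    def test_missing_level_rejected(self, rng):
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=8)
        p = fpn.topdown_fuse(tiny_levels(rng))
        del p["p3"]
        with pytest.raises(ValueError, match="p3"):
            fpn.smooth_and_splice(p)

    def test_stride_mismatch_rejected(self, rng):
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=8)
        levels = tiny_levels(rng)
        levels["c3"] = Tensor(levels["c3"].data[:, :, :10, :10])
        with pytest.raises(ValueError, match="stride"):
            fpn.topdown_fuse(levels)

    def test_sum_splice_mode_shape(self, rng):
        fpn = FeaturePyramidFusion(BackboneConfig.tiny().out_channels,
                                   fpn_channels=8, splice_mode="sum")
        fused = fpn(tiny_levels(rng))
        assert fused.shape == (2, 8, 32, 32)
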