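"""Feature-pyramid fusion: nearest-neighbour coordinate transform, lateral
1x1 projections, top-down 2x-upsampled summation, and the splice of all
pyramid levels into one fused feature map.

The pyramid convention follows the standard multi-scale feature layout: the
backbone emits levels ``{c2, c3, c4, c5}`` at strides ``{4, 8, 16, 32}`` of
the input image; fusion produces ``{p2, p3, p4, p5}`` at the same strides,
all with a common channel width.  "Splice" resizes p3..p5 to p2's resolution
(nearest neighbour) and concatenates along the channel axis, so a 128x128
input yields a [B, 4*fpn_channels, 32, 32] fused map.
"""

from __future__ import annotations

import numpy as np

from . import nn as _nn
from .nn import Tensor

__all__ = [
    "nn_coord", "resize_nearest", "upsample_nearest_2x",
    "FeaturePyramidFusion", "PYRAMID_LEVELS", "LEVEL_STRIDES",
]

PYRAMID_LEVELS = ("p2", "p3", "p4", "p5")
LEVEL_STRIDES = {"c2": 4, "c3": 8, "c4": 16, "c5": 32,
                 "p2": 4, "p3": 8, "p4": 16, "p5": 32}


def nn_coord(dst_x: int, dst_y: int, src_w: int, src_h: int,
             dst_w: int, dst_h: int) -> tuple[int, int]:
    """Map a destination pixel to its nearest-neighbour source pixel.

    The real-valued source coordinate is ``dstX * (srcW / dstW)`` (and
    likewise for y); the integer index is its floor, clamped to the valid
    range.
    """
    for name, v in (("srcW", src_w), ("srcH", src_h),
                    ("dstW", dst_w), ("dstH", dst_h)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if not (0 <= dst_x < dst_w) or not (0 <= dst_y < dst_h):
        raise ValueError(f"destination coordinate ({dst_x}, {dst_y}) outside "
                         f"[0, {dst_w}) x [0, {dst_h})")
    src_x = int(np.floor(dst_x * (src_w / dst_w)))
    src_y = int(np.floor(dst_y * (src_h / dst_h)))
    return min(src_x, src_w - 1), min(src_y, src_h - 1)


def _nn_index(dst_n: int, src_n: int) -> np.ndarray:
    idx = np.floor(np.arange(dst_n) * (src_n / dst_n)).astype(np.intp)
    return np.minimum(idx, src_n - 1)


def resize_nearest(image: np.ndarray, dst_h: int, dst_w: int) -> np.ndarray:
    """Nearest-neighbour resize of the trailing two axes of ``image``."""
    if dst_h < 1 or dst_w < 1:
        raise ValueError("target size must be positive")
    src_h, src_w = image.shape[-2], image.shape[-1]
    iy = _nn_index(dst_h, src_h)
    ix = _nn_index(dst_w, src_w)
    return np.ascontiguousarray(image[..., iy[:, None], ix[None, :]])


def upsample_nearest_2x(x):
    """Double the spatial size of a [B, C, H, W] map by 2x2 replication.

    Accepts a numpy array or a Tensor; returns the same kind.  Equivalent to
    applying :func:`nn_coord` per output pixel with dst = 2 * src.
    """
    if isinstance(x, Tensor):
        return x.upsample_nearest2x()
    x = np.asarray(x)
    return x.repeat(2, axis=-2).repeat(2, axis=-1)


class FeaturePyramidFusion(_nn.Module):
    """Lateral projection + top-down fusion + smoothing + splice.

    Parameters
    ----------
    in_channels : channel widths of (c2, c3, c4, c5) from the backbone.
    fpn_channels : common width of the fused levels (default 256).
    splice_mode : "concat" (default) stacks the resized levels along the
        channel axis; "sum" adds them instead.
    """

    def __init__(self, in_channels: tuple[int, int, int, int],
                 fpn_channels: int = 256, splice_mode: str = "concat",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if splice_mode not in ("concat", "sum"):
            raise ValueError(f"unknown splice_mode {splice_mode!r}")
        rng = rng or np.random.default_rng(0)
        self.fpn_channels = fpn_channels
        self.splice_mode = splice_mode
        self.lateral = [_nn.Conv2d(c, fpn_channels, 1, rng=rng)
                        for c in in_channels]          # for c2..c5
        # p5 smoothed with 1x1; p2..p4 with 3x3 (padding keeps spatial size)
        self.smooth5 = _nn.Conv2d(fpn_channels, fpn_channels, 1, rng=rng)
        self.smooth = [_nn.Conv2d(fpn_channels, fpn_channels, 3, padding=1, rng=rng)
                       for _ in range(3)]              # for p2, p3, p4

    # -- stages -----------------------------------------------------------
    def lateral_project(self, c_level: Tensor, level: int) -> Tensor:
        """1x1-convolve a c-level (2..5) to the common channel width."""
        return self.lateral[level - 2](c_level)

    def topdown_fuse(self, c_levels: dict[str, Tensor]) -> dict[str, Tensor]:
        """p5 = lateral(c5); p_i = lateral(c_i) + upsample2x(p_{i+1})."""
        for i in range(2, 5):
            hi, lo = c_levels[f"c{i}"], c_levels[f"c{i + 1}"]
            if (hi.shape[-2] != 2 * lo.shape[-2]
                    or hi.shape[-1] != 2 * lo.shape[-1]):
                raise ValueError(
                    f"stride mismatch between c{i} {hi.shape} and "
                    f"c{i + 1} {lo.shape}: expected a factor-2 relation")
        p = {"p5": self.lateral_project(c_levels["c5"], 5)}
        for i in (4, 3, 2):
            up = p[f"p{i + 1}"].upsample_nearest2x()
            p[f"p{i}"] = self.lateral_project(c_levels[f"c{i}"], i) + up
        return p

    def smooth_and_splice(self, p_levels: dict[str, Tensor]) -> Tensor:
        missing = [k for k in PYRAMID_LEVELS if k not in p_levels]
        if missing:
            raise ValueError(f"missing pyramid levels: {missing}")
        s = {"p5": self.smooth5(p_levels["p5"])}
        for i, lvl in enumerate(("p2", "p3", "p4")):
            s[lvl] = self.smooth[i](p_levels[lvl])
        # resize everything to p2's resolution by repeated 2x replication
        pieces = [s["p2"]]
        for lvl, reps in (("p3", 1), ("p4", 2), ("p5", 3)):
            t = s[lvl]
            for _ in range(reps):
                t = t.upsample_nearest2x()
            pieces.append(t)
        if self.splice_mode == "sum":
            out = pieces[0]
            for t in pieces[1:]:
                out = out + t
            return out
        return _nn.concat(pieces, axis=1)

    def forward(self, c_levels: dict[str, Tensor]) -> Tensor:
        return self.smooth_and_splice(self.topdown_fuse(c_levels))
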