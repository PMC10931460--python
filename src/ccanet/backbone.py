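"""Residual bottleneck backbone (50- and 101-layer plans) emitting c2..c5.

The stem is a 7x7 stride-2 convolution followed by a 2x2 stride-2 max pool,
so the first stage output (c2) sits at stride 4 of the input; the remaining
stages halve resolution, giving strides {4, 8, 16, 32}.  Depth selects the
standard block counts ([3,4,6,3] for 50 layers, [3,4,23,3] for 101); the
bottleneck inner widths are configurable so width-reduced variants can be
trained at desk scale, with the standard widths (64, 128, 256, 512) as the
default.  Each bottleneck expands its inner width by 4.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn as _nn
from .nn import Tensor

__all__ = ["BackboneConfig", "Bottleneck", "ResidualBackbone",
           "BLOCK_PLANS", "EXPANSION"]

BLOCK_PLANS = {50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}
EXPANSION = 4


@dataclasses.dataclass(frozen=True)
class BackboneConfig:
    """Depth (50 or 101) plus optional width reduction."""

    depth: int = 50
    stem_channels: int = 64
    inner_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.depth not in BLOCK_PLANS:
            raise ValueError(f"depth must be one of {sorted(BLOCK_PLANS)}, "
                             f"got {self.depth}")
        if len(self.inner_widths) != 4:
            raise ValueError("inner_widths must have 4 entries")

    @property
    def blocks(self) -> tuple[int, int, int, int]:
        return BLOCK_PLANS[self.depth]

    @property
    def out_channels(self) -> tuple[int, int, int, int]:
        """Channel widths of (c2, c3, c4, c5)."""
        return tuple(EXPANSION * w for w in self.inner_widths)

    @classmethod
    def tiny(cls, depth: int = 50) -> "BackboneConfig":
        """Width-reduced plan for CPU-scale experiments."""
        return cls(depth=depth, stem_channels=8, inner_widths=(4, 8, 16, 32))


class Bottleneck(_nn.Module):
    """1x1 reduce -> 3x3 (optionally strided) -> 1x1 expand, with skip."""

    def __init__(self, in_ch: int, inner: int, stride: int, eps: float,
                 rng: np.random.Generator):
        super().__init__()
        out_ch = inner * EXPANSION
        self.conv1 = _nn.Conv2d(in_ch, inner, 1, bias=False, rng=rng)
        self.bn1 = _nn.BatchNorm2d(inner, eps=eps)
        self.conv2 = _nn.Conv2d(inner, inner, 3, stride=stride, padding=1,
                                bias=False, rng=rng)
        self.bn2 = _nn.BatchNorm2d(inner, eps=eps)
        self.conv3 = _nn.Conv2d(inner, out_ch, 1, bias=False, rng=rng)
        self.bn3 = _nn.BatchNorm2d(out_ch, eps=eps)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = _nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                        bias=False, rng=rng)
            self.down_bn = _nn.BatchNorm2d(out_ch, eps=eps)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (h + skip).relu()


class ResidualBackbone(_nn.Module):
    def __init__(self, config: BackboneConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config or BackboneConfig()
        rng = rng or np.random.default_rng(0)
        cfg = self.config
        self.stem_conv = _nn.Conv2d(3, cfg.stem_channels, 7, stride=2,
                                    padding=3, bias=False, rng=rng)
        self.stem_bn = _nn.BatchNorm2d(cfg.stem_channels, eps=cfg.bn_eps)
        stages = []
        in_ch = cfg.stem_channels
        for s, (n_blocks, inner) in enumerate(zip(cfg.blocks, cfg.inner_widths)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(Bottleneck(in_ch, inner, stride, cfg.bn_eps, rng))
                in_ch = inner * EXPANSION
            stages.append(blocks)
        self.stage1, self.stage2, self.stage3, self.stage4 = stages

    def forward(self, images: Tensor) -> dict[str, Tensor]:
        """[B, 3, H, W] -> {c2..c5}; H and W must be divisible by 32."""
        b, c, h, w = images.shape
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size must be divisible by 32 (the c5 stride), "
                f"got {h}x{w}")
        x = self.stem_bn(self.stem_conv(images)).relu().maxpool2d(2, 2)
        out = {}
        for name, stage in (("c2", self.stage1), ("c3", self.stage2),
                            ("c4", self.stage3), ("c5", self.stage4)):
            for block in stage:
                x = block(x)
            out[name] = x
        return out
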