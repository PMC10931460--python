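"""The end-to-end severity regressor: backbone -> pyramid fusion ->
channel attention -> global average pooling -> fully connected score head.

The attention unit is applied once to the spliced pyramid output by default
(``placement="post_fpn"``); ``placement="per_block"`` instead attaches one
unit to each backbone stage output before fusion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn as _nn
from .attention import ATTENTION_VARIANTS, build_attention
from .backbone import BackboneConfig, ResidualBackbone
from .fpn import FeaturePyramidFusion
from .nn import Tensor

__all__ = ["DepressionRegressor", "build_model"]


class DepressionRegressor(_nn.Module):
    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 attention_variant: str = "cca", fpn_channels: int = 256,
                 attention_r: int = 16, attention_k: int = 5,
                 placement: str = "post_fpn", splice_mode: str = "concat",
                 seed: int = 0):
        super().__init__()
        if attention_variant not in ATTENTION_VARIANTS:
            raise ValueError(f"unknown attention variant {attention_variant!r}; "
                             f"choose from {ATTENTION_VARIANTS}")
        if placement not in ("post_fpn", "per_block"):
            raise ValueError(f"placement must be post_fpn or per_block, "
                             f"got {placement!r}")
        self.meta = {"attention_variant": attention_variant,
                     "fpn_channels": fpn_channels, "attention_r": attention_r,
                     "attention_k": attention_k, "placement": placement,
                     "splice_mode": splice_mode, "seed": seed}
        cfg = backbone_cfg or BackboneConfig()
        self.backbone_cfg = cfg
        rng = np.random.default_rng(seed)
        self.backbone = ResidualBackbone(cfg, rng=rng)
        self.fpn = FeaturePyramidFusion(cfg.out_channels,
                                        fpn_channels=fpn_channels,
                                        splice_mode=splice_mode, rng=rng)
        fused_ch = 4 * fpn_channels if splice_mode == "concat" else fpn_channels
        self.placement = placement
        if placement == "per_block":
            self.block_attn = [build_attention(attention_variant, c,
                                               r=attention_r, k=attention_k,
                                               rng=rng)
                               for c in cfg.out_channels]
            from .attention import IdentityUnit
            self.attn = IdentityUnit()
        else:
            self.block_attn = []
            self.attn = build_attention(attention_variant, fused_ch,
                                        r=attention_r, k=attention_k, rng=rng)
        self.head = _nn.Linear(fused_ch, 1, rng=rng)

    def forward(self, images: Tensor) -> Tensor:
        """[B, 3, H, W] -> [B, 1] predicted BDI-II scores."""
        c_levels = self.backbone(images)
        if self.placement == "per_block":
            for i, name in enumerate(("c2", "c3", "c4", "c5")):
                c_levels[name] = self.block_attn[i](c_levels[name])
        fused = self.fpn(c_levels)
        fused = self.attn(fused)
        pooled = fused.mean(axis=(2, 3))
        return self.head(pooled)

    # -- checkpointing ---------------------------------------------------
    def save(self, path: str | Path,
             norm_stats: tuple[np.ndarray, np.ndarray] | None = None,
             extra: dict | None = None) -> None:
        header = {"kind": "depression_regressor", "format_version": 1,
                  "meta": self.meta,
                  "backbone": {"depth": self.backbone_cfg.depth,
                               "stem_channels": self.backbone_cfg.stem_channels,
                               "inner_widths": list(self.backbone_cfg.inner_widths)},
                  "extra": extra or {}}
        arrays = self.state_dict()
        if norm_stats is not None:
            arrays["norm:mean"], arrays["norm:std"] = norm_stats
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path
             ) -> tuple["DepressionRegressor", tuple[np.ndarray, np.ndarray] | None, dict]:
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            meta = header["meta"]
            bb = header["backbone"]
            model = cls(BackboneConfig(depth=bb["depth"],
                                       stem_channels=bb["stem_channels"],
                                       inner_widths=tuple(bb["inner_widths"])),
                        attention_variant=meta["attention_variant"],
                        fpn_channels=meta["fpn_channels"],
                        attention_r=meta["attention_r"],
                        attention_k=meta["attention_k"],
                        placement=meta["placement"],
                        splice_mode=meta["splice_mode"], seed=meta["seed"])
            state = {k: data[k] for k in data.files
                     if k not in ("__header__", "norm:mean", "norm:std")}
            model.load_state_dict(state)
            norm = None
            if "norm:mean" in data.files:
                norm = (data["norm:mean"], data["norm:std"])
        return model, norm, header.get("extra", {})


def build_model(backbone_cfg: BackboneConfig | None = None,
                attention_variant: str = "cca", **kwargs) -> DepressionRegressor:
    """Convenience constructor mirroring the ablation variant names."""
    return DepressionRegressor(backbone_cfg, attention_variant, **kwargs)
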