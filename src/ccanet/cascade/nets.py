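"""The three cascade stage networks: proposal, refinement, output.

All feature-extraction convolutions are 3x3 stride 1 and all pooling is 2x2
stride 2; the prediction heads are 1x1 (proposal stage) or fully connected
(refine/output stages).  Each stage has three heads: face classification
(2 logits), box regression (4), and landmark regression (10, in window
units).  The proposal network is fully convolutional, so it can sweep an
arbitrary-sized pyramid level; its total stride is 2 and its receptive field
is 12 pixels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .. import nn as _nn
from ..nn import Tensor

__all__ = ["PNet", "RNet", "ONet", "StageNets",
           "PNET_INPUT", "RNET_INPUT", "ONET_INPUT"]

PNET_INPUT = 12
RNET_INPUT = 24
ONET_INPUT = 48


class PNet(_nn.Module):
    """Fully convolutional proposal network (12x12 receptive field)."""

    stride = 2
    window = PNET_INPUT

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1 = _nn.Conv2d(3, 10, 3, rng=rng)
        self.c2 = _nn.Conv2d(10, 16, 3, rng=rng)
        self.c3 = _nn.Conv2d(16, 32, 3, rng=rng)
        self.head_cls = _nn.Conv2d(32, 2, 1, rng=rng)
        self.head_box = _nn.Conv2d(32, 4, 1, rng=rng)
        self.head_lm = _nn.Conv2d(32, 10, 1, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h = self.c1(x).relu().maxpool2d(2, 2)
        h = self.c2(h).relu()
        h = self.c3(h).relu()
        return self.head_cls(h), self.head_box(h), self.head_lm(h)


class _CropNet(_nn.Module):
    """Shared plan of the refine/output stages: conv stack + fc heads."""

    def __init__(self, widths: tuple[int, ...], pools: tuple[bool, ...],
                 flat: int, fc_width: int, rng: np.random.Generator):
        super().__init__()
        chans = (3,) + widths
        self.convs = [_nn.Conv2d(chans[i], chans[i + 1], 3, rng=rng)
                      for i in range(len(widths))]
        self.pools = pools
        self.fc = _nn.Linear(flat, fc_width, rng=rng)
        self.head_cls = _nn.Linear(fc_width, 2, rng=rng)
        self.head_box = _nn.Linear(fc_width, 4, rng=rng)
        self.head_lm = _nn.Linear(fc_width, 10, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h = x
        for conv, pool in zip(self.convs, self.pools):
            h = conv(h).relu()
            if pool:
                h = h.maxpool2d(2, 2)
        b = h.shape[0]
        h = h.reshape(b, -1)
        h = self.fc(h).relu()
        return self.head_cls(h), self.head_box(h), self.head_lm(h)


class RNet(_CropNet):
    """Refinement network on 24x24 crops."""

    window = RNET_INPUT

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        # 24 -> 22 -> 11 -> 9 -> 4 -> 2
        super().__init__(widths=(28, 48, 64), pools=(True, True, False),
                         flat=64 * 2 * 2, fc_width=128, rng=rng)

    def forward(self, x):
        h = self.convs[0](x).relu().maxpool2d(2, 2)   # 22 -> 11
        h = self.convs[1](h).relu().maxpool2d(2, 2)   # 9 -> 4
        h = self.convs[2](h).relu()                   # 2
        b = h.shape[0]
        h = self.fc(h.reshape(b, -1)).relu()
        return self.head_cls(h), self.head_box(h), self.head_lm(h)


class ONet(_CropNet):
    """Output network on 48x48 crops (final boxes + 5 landmarks)."""

    window = ONET_INPUT

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        # 48 -> 46 -> 23 -> 21 -> 10 -> 8 -> 4 -> 2
        super().__init__(widths=(32, 64, 64, 128), pools=(True, True, True, False),
                         flat=128 * 2 * 2, fc_width=256, rng=rng)


class StageNets:
    """Container for the trained P/R/O nets with checkpoint persistence."""

    FORMAT_VERSION = 1

    def __init__(self, pnet: PNet, rnet: RNet, onet: ONet):
        self.pnet = pnet
        self.rnet = rnet
        self.onet = onet

    @classmethod
    def fresh(cls, seed: int = 0) -> "StageNets":
        ss = np.random.SeedSequence(seed)
        rp, rr, ro = (np.random.default_rng(c) for c in ss.spawn(3))
        return cls(PNet(rng=rp), RNet(rng=rr), ONet(rng=ro))

    def eval(self) -> "StageNets":
        for net in (self.pnet, self.rnet, self.onet):
            net.eval()
        return self

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for tag, net in (("pnet", self.pnet), ("rnet", self.rnet),
                         ("onet", self.onet)):
            for k, v in net.state_dict().items():
                arrays[f"{tag}/{k}"] = v
        header = json.dumps({"format_version": self.FORMAT_VERSION,
                             "kind": "cascade_stage_nets"})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "StageNets":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("format_version") != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint format: {header}")
            nets = cls.fresh(0)
            for tag, net in (("pnet", nets.pnet), ("rnet", nets.rnet),
                             ("onet", nets.onet)):
                state = {k.split("/", 1)[1]: data[k] for k in data.files
                         if k.startswith(tag + "/")}
                net.load_state_dict(state)
        return nets
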