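"""Training of the cascade stage networks on synthetic patch sets.

Each stage is trained independently on patches rendered at its input size
(12 / 24 / 48 pixels) with the weighted multi-task objective: binary
cross-entropy for face/background samples, squared-norm box regression for
face and part-face samples, squared-norm landmark regression for face
samples.  Sample-type indicators (beta) gate which loss terms a sample
contributes to; task weights (alpha) come from the cascade configuration.
"""

from __future__ import annotations

import numpy as np

from ..nn import Adam, Tensor
from ..synthetic import DetectionPatchSet, make_detection_patches
from .nets import ONET_INPUT, PNET_INPUT, RNET_INPUT, ONet, PNet, RNet, StageNets
from .pyramid import CascadeConfig

__all__ = ["train_stage", "train_cascade", "batch_objective"]

_CLS_EPS = 1e-6


def batch_objective(net, images: np.ndarray, patches: DetectionPatchSet,
                    idx: np.ndarray, alpha: tuple[float, float, float]) -> Tensor:
    """Differentiable mean multi-task objective over one batch."""
    x = Tensor(images[idx])
    cls, box, lm = net(x)
    n = len(idx)
    if cls.ndim == 4:   # proposal net emits [N, C, 1, 1] maps on 12x12 input
        cls = cls.reshape(n, 2)
        box = box.reshape(n, 4)
        lm = lm.reshape(n, 10)

    y = (patches.cls_label[idx] == 1).astype(np.float32)
    beta = patches.beta[idx].astype(np.float32)

    # face probability via the two-logit softmax == sigmoid of the logit gap
    z = cls.narrow(1, 1, 1) - cls.narrow(1, 0, 1)
    p = z.sigmoid() * (1.0 - 2.0 * _CLS_EPS) + _CLS_EPS
    p = p.reshape(n)
    bce = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    l_det = (bce * Tensor(beta[:, 0])).sum()

    t_box = np.nan_to_num(patches.box_offsets[idx]).astype(np.float32)
    l_box = (((box - Tensor(t_box)) ** 2.0).sum(axis=1)
             * Tensor(beta[:, 1])).sum()

    t_lm = np.nan_to_num(patches.landmarks[idx]).astype(np.float32)
    l_lm = (((lm - Tensor(t_lm)) ** 2.0).sum(axis=1)
            * Tensor(beta[:, 2])).sum()

    return (alpha[0] * l_det + alpha[1] * l_box + alpha[2] * l_lm) * (1.0 / n)


def train_stage(net, patches: DetectionPatchSet,
                alpha: tuple[float, float, float], epochs: int = 10,
                batch_size: int = 128, lr: float = 1e-3, seed: int = 0
                ) -> list[float]:
    """Train one stage net; returns per-epoch mean objective values."""
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=lr)
    n = len(patches)
    images = patches.images
    history = []
    net.train()
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            loss = batch_objective(net, images, patches, idx, alpha)
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        history.append(total / n)
        if not np.isfinite(history[-1]):
            raise FloatingPointError("stage training diverged (non-finite loss)")
    net.eval()
    return history


def train_cascade(n_face: int = 800, n_nonface: int = 800, n_part: int = 400,
                  epochs: int = 10, seed: int = 0,
                  config: CascadeConfig | None = None
                  ) -> tuple[StageNets, dict[str, list[float]]]:
    """Train all three stages on freshly sampled synthetic patches."""
    config = config or CascadeConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(7)]
    nets = StageNets(PNet(rng=np.random.default_rng(seeds[0])),
                     RNet(rng=np.random.default_rng(seeds[1])),
                     ONet(rng=np.random.default_rng(seeds[2])))
    history = {}
    plan = [
        ("pnet", nets.pnet, PNET_INPUT, config.alpha_pnet, seeds[3]),
        ("rnet", nets.rnet, RNET_INPUT, config.alpha_rnet, seeds[4]),
        ("onet", nets.onet, ONET_INPUT, config.alpha_onet, seeds[5]),
    ]
    for name, net, size, alpha, stage_seed in plan:
        patches = make_detection_patches(n_face, n_nonface, n_part,
                                         patch_size=size, seed=stage_seed)
        history[name] = train_stage(net, patches, alpha, epochs=epochs,
                                    seed=stage_seed)
    return nets, history
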