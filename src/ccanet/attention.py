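"""Channel attention units: the cross-channel attention (CCA) gate and the
SE / ECA / CBAM baselines behind one interface.

The CCA gate composes four steps on a [B, C, H, W] feature map:

1. global average pooling over the spatial axes -> channel descriptor z,
2. a bottleneck fully connected gate S = sigmoid(W2 . relu(W1 . z)) with
   reduction ratio r (W1: C/r x C, W2: C x C/r, no biases),
3. a 1-D convolution of odd size k across the channel axis followed by a
   second sigmoid, omega = sigmoid(conv1d_k(S)), giving local cross-channel
   interaction,
4. channel-wise rescaling x~_c = x_c * omega_c.

Both sigmoids are applied (the gate output is squashed twice by design), so
every channel weight lies strictly inside (0, 1) and the unit can only
attenuate.  Functional numpy forms (``gap``, ``fc_gate``, ``conv_gate``,
``rescale``, ``cca_forward``) expose the arithmetic for direct verification;
the ``*Unit`` modules wrap the same computation with trainable parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn as _nn
from .nn import Tensor

__all__ = [
    "CCAParams", "gap", "fc_gate", "conv_gate", "rescale", "cca_forward",
    "se_forward", "eca_forward",
    "CCAUnit", "SEUnit", "ECAUnit", "CBAMUnit", "IdentityUnit",
    "build_attention", "ATTENTION_VARIANTS",
]

ATTENTION_VARIANTS = ("none", "se", "eca", "cbam", "cca")


# ---------------------------------------------------------------------------
# functional forms (numpy)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CCAParams:
    """Parameters of the CCA gate.

    ``W1`` is (C/r, C); ``W2`` is (C, C/r) — the expansion back to C, so the
    gate output matches the channel count.  ``conv_kernel`` has odd length k
    (default 5); ``conv_bias`` may be None to disable the bias term.
    """

    W1: np.ndarray
    W2: np.ndarray
    conv_kernel: np.ndarray
    conv_bias: float | None = 0.0
    r: int = 16

    def __post_init__(self) -> None:
        cr, c = self.W1.shape
        if self.W2.shape != (c, cr):
            raise ValueError(f"W2 must be {(c, cr)} (C x C/r), got {self.W2.shape}")
        if c % self.r or c // self.r != cr:
            raise ValueError(f"r={self.r} must divide C={c} with C/r={cr}")
        if len(self.conv_kernel) % 2 == 0:
            raise ValueError("conv kernel size must be odd")

    @classmethod
    def random(cls, channels: int, r: int = 16, k: int = 5,
               seed: int = 0) -> "CCAParams":
        rng = np.random.default_rng(seed)
        cr = channels // r
        return cls(W1=rng.normal(0, 1 / np.sqrt(channels), (cr, channels)),
                   W2=rng.normal(0, 1 / np.sqrt(max(cr, 1)), (channels, cr)),
                   conv_kernel=rng.normal(0, 1 / np.sqrt(k), k),
                   conv_bias=0.0, r=r)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def gap(x: np.ndarray) -> np.ndarray:
    """Global average pooling: [B, C, H, W] -> per-channel means [B, C]."""
    x = np.asarray(x)
    return x.mean(axis=(2, 3))


def fc_gate(z: np.ndarray, params: CCAParams) -> np.ndarray:
    """Bottleneck gate S = sigmoid(W2 . relu(W1 . z)), per batch row."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != params.W1.shape[1]:
        raise ValueError(f"descriptor length {z.shape[1]} does not match "
                         f"W1 columns {params.W1.shape[1]}")
    hidden = np.maximum(z @ params.W1.T, 0.0)
    return _sigmoid(hidden @ params.W2.T)


def conv_gate(s: np.ndarray, params: CCAParams) -> np.ndarray:
    """omega = sigmoid(conv1d_k(S)) across the channel axis, zero padded."""
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    k = len(params.conv_kernel)
    pad = (k - 1) // 2
    sp = np.pad(s, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(sp, k, axis=1)
    out = win @ params.conv_kernel
    if params.conv_bias is not None:
        out = out + params.conv_bias
    return _sigmoid(out)


def rescale(x: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling x~_c = x_c * omega_c."""
    x = np.asarray(x)
    omega = np.asarray(omega)
    if omega.ndim == 1:
        omega = omega[None, :]
    if omega.shape[1] != x.shape[1]:
        raise ValueError(f"omega length {omega.shape[1]} does not match "
                         f"channel count {x.shape[1]}")
    return x * omega[:, :, None, None]


def cca_forward(x: np.ndarray, params: CCAParams) -> np.ndarray:
    """The full CCA unit, computed independently per batch element."""
    return rescale(x, conv_gate(fc_gate(gap(x), params), params))


def se_forward(x: np.ndarray, params: CCAParams) -> np.ndarray:
    """SE baseline: the bottleneck gate alone (no cross-channel conv)."""
    return rescale(x, fc_gate(gap(x), params))


def eca_forward(x: np.ndarray, params: CCAParams) -> np.ndarray:
    """ECA baseline: CCA with the bottleneck gate replaced by identity."""
    return rescale(x, conv_gate(gap(x), params))


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

class IdentityUnit(_nn.Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class _GapMixin:
    @staticmethod
    def _gap(x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))

    @staticmethod
    def _scale(x: Tensor, omega: Tensor) -> Tensor:
        b, c = omega.shape
        return x * omega.reshape(b, c, 1, 1)


class SEUnit(_nn.Module, _GapMixin):
    """Squeeze-and-excitation: gap -> bottleneck sigmoid gate -> rescale."""

    def __init__(self, channels: int, r: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % r:
            raise ValueError(f"reduction ratio {r} must divide channels {channels}")
        rng = rng or np.random.default_rng(0)
        self.fc1 = _nn.Linear(channels, channels // r, bias=False, rng=rng)
        self.fc2 = _nn.Linear(channels // r, channels, bias=False, rng=rng)

    def gate(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return self._scale(x, self.gate(self._gap(x)))


class ECAUnit(_nn.Module, _GapMixin):
    """Efficient channel attention: gap -> k-sized 1-D conv -> sigmoid."""

    def __init__(self, channels: int, k: int = 5, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = _nn.Conv1dChannels(k, bias=bias,
                                       rng=rng or np.random.default_rng(0))

    def forward(self, x: Tensor) -> Tensor:
        omega = self.conv(self._gap(x)).sigmoid()
        return self._scale(x, omega)


class CCAUnit(_nn.Module, _GapMixin):
    """Cross-channel attention: SE-style gate then 1-D conv, both sigmoided."""

    def __init__(self, channels: int, r: int = 16, k: int = 5,
                 conv_bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % r:
            raise ValueError(f"reduction ratio {r} must divide channels {channels}")
        rng = rng or np.random.default_rng(0)
        self.fc1 = _nn.Linear(channels, channels // r, bias=False, rng=rng)
        self.fc2 = _nn.Linear(channels // r, channels, bias=False, rng=rng)
        self.conv = _nn.Conv1dChannels(k, bias=conv_bias, rng=rng)

    def params(self) -> CCAParams:
        """Snapshot of the unit's weights in the functional form."""
        c = self.fc1.weight.shape[0]
        r = c // self.fc1.weight.shape[1]
        return CCAParams(
            W1=self.fc1.weight.data.T.astype(np.float64),
            W2=self.fc2.weight.data.T.astype(np.float64),
            conv_kernel=self.conv.weight.data.ravel().astype(np.float64),
            conv_bias=None if self.conv.bias is None
            else float(self.conv.bias.data[0]),
            r=r)

    def forward(self, x: Tensor) -> Tensor:
        s = self.fc2(self.fc1(self._gap(x)).relu()).sigmoid()
        omega = self.conv(s).sigmoid()
        return self._scale(x, omega)


class CBAMUnit(_nn.Module, _GapMixin):
    """Convolutional block attention: channel gate (avg+max pooling through a
    shared bottleneck MLP) followed by a spatial gate (7x7 conv over the
    stacked channel-mean and channel-max maps)."""

    def __init__(self, channels: int, r: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % r:
            raise ValueError(f"reduction ratio {r} must divide channels {channels}")
        rng = rng or np.random.default_rng(0)
        self.fc1 = _nn.Linear(channels, channels // r, bias=True, rng=rng)
        self.fc2 = _nn.Linear(channels // r, channels, bias=True, rng=rng)
        self.spatial = _nn.Conv2d(2, 1, spatial_kernel,
                                  padding=(spatial_kernel - 1) // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        avg = self._gap(x)
        mx = x.reshape(b, c, h * w).max(axis=2)
        gate = (self.fc2(self.fc1(avg).relu())
                + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = self._scale(x, gate)
        ch_avg = x.mean(axis=1, keepdims=True)
        ch_max = x.max(axis=1, keepdims=True)
        sp = self.spatial(_nn.concat([ch_avg, ch_max], axis=1)).sigmoid()
        return x * sp


def build_attention(variant: str, channels: int, r: int = 16, k: int = 5,
                    rng: np.random.Generator | None = None) -> _nn.Module:
    """Factory over the five ablation variants."""
    variant = variant.lower()
    if variant == "none":
        return IdentityUnit()
    if variant == "se":
        return SEUnit(channels, r=r, rng=rng)
    if variant == "eca":
        return ECAUnit(channels, k=k, rng=rng)
    if variant == "cbam":
        return CBAMUnit(channels, r=r, rng=rng)
    if variant == "cca":
        return CCAUnit(channels, r=r, k=k, rng=rng)
    raise ValueError(f"unknown attention variant {variant!r}; "
                     f"choose from {ATTENTION_VARIANTS}")
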