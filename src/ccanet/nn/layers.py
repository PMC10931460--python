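"""Neural-network building blocks on top of the autodiff engine.

Modules hold :class:`~ccanet.nn.autodiff.Tensor` parameters (float32) and
non-trainable numpy buffers (batch-norm running statistics).  ``state_dict`` /
``load_state_dict`` serialise both, so checkpoints round-trip through ``npz``
files.  Parameter initialisation is He-style and fully determined by the
``rng`` handed to the constructor.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Parameter", "Conv2d", "Linear", "BatchNorm2d",
    "Conv1dChannels", "Sequential", "ReLU",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: child modules / parameters are discovered via attributes."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({"buf:" + name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, val in state.items():
            if key.startswith("buf:"):
                buf = buffers[key[4:]]
                buf[...] = val
            else:
                p = params[key]
                if p.data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {val.shape}")
                p.data = val.astype(p.data.dtype).copy()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalisation over [B,C,H,W] (also accepts [B,C])."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return x.batchnorm(self.gamma, self.beta,
                           running_mean=self.running_mean,
                           running_var=self.running_var,
                           training=self.training, momentum=self.momentum,
                           eps=self.eps)


class Conv1dChannels(Module):
    """Length-preserving 1-D convolution across the channel axis of [B, C].

    Used by the attention gates: a kernel of odd size ``k`` slides over the
    channel descriptor with symmetric zero padding (k-1)/2.
    """

    def __init__(self, kernel: int = 5, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"channel convolution kernel must be odd, got {kernel}")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / kernel)
        # stored as a conv2d kernel [1, 1, 1, k] acting on [B, 1, 1, C]
        self.weight = Parameter(rng.normal(0.0, std, (1, 1, 1, kernel)))
        self.bias = Parameter(np.zeros(1)) if bias else None
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape
        pad = (self.kernel - 1) // 2
        y = x.reshape(b, 1, 1, c)
        # symmetric zero padding along channels only: pad W axis via conv padding
        # conv2d pads both H and W; H is size 1, so pad manually on W
        data = y  # [B,1,1,C]
        out = _conv_w_only(data, self.weight, self.bias, pad)
        return out.reshape(b, c)


def _conv_w_only(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int) -> Tensor:
    """conv2d with padding applied only along the last axis."""
    b, c, h, w = x.shape
    if pad:
        zeros = Tensor(np.zeros((b, c, h, pad), dtype=x.data.dtype))
        from .autodiff import concat
        x = concat([zeros, x, zeros], axis=3)
    return x.conv2d(weight, bias, stride=1, padding=0)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()
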