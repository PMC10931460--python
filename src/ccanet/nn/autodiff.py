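"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded tape in reverse topological
order and accumulates gradients.  Only the operations needed by the models in
this package are provided (elementwise arithmetic, matmul, 2-D convolution via
im2col, max pooling, batch normalisation, nearest-neighbour upsampling,
reductions, concatenation).  Convolution and batch normalisation are fused
primitives with analytic backward passes; everything else composes.

Arrays are kept in whatever float dtype they arrive in (models use float32;
gradient-check tests use float64).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable in both tails
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        s[~pos] = e / (1.0 + e)

        def backward(g: np.ndarray) -> None:
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * e)

        return self._make(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        def backward(g: np.ndarray) -> None:
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % len(in_shape) for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accum(np.broadcast_to(gg, in_shape).copy()
                        if np.isscalar(gg) or gg.shape != in_shape
                        else gg)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # distribute gradient over ties equally for determinism
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g: np.ndarray) -> None:
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(gg * mask / counts)

        res = out_data if keepdims else out_data.squeeze(axis)
        return self._make(res, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g: np.ndarray) -> None:
            self._accum(g.reshape(in_shape))

        return self._make(out_data, (self,), backward)

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        """Slice ``length`` entries from ``start`` along ``axis``."""
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def backward(g: np.ndarray) -> None:
            gx = np.zeros_like(self.data)
            gx[sl] = g
            self._accum(gx)

        return self._make(self.data[sl].copy(), (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g: np.ndarray) -> None:
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- spatial ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """Cross-correlation of [B,C,H,W] with [O,C,kh,kw] kernels."""
        x = self.data
        w = weight.data
        B, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        Hp, Wp = xp.shape[2], xp.shape[3]
        OH = (Hp - kh) // stride + 1
        OW = (Wp - kw) // stride + 1
        if OH < 1 or OW < 1:
            raise ValueError(f"conv2d: input {H}x{W} too small for kernel {kh}x{kw}")
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = win[:, :, ::stride, ::stride]  # [B,C,OH,OW,kh,kw]
        out = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # [B,OH,OW,O]
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if bias is not None:
            out += bias.data.reshape(1, O, 1, 1)

        def backward(g: np.ndarray) -> None:
            if weight.requires_grad:
                gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3]))
                weight._accum(gw)  # [O,C,kh,kw]
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        # [B,OH,OW,C]
                        gij = np.tensordot(g, w[:, :, i, j], axes=([1], [0]))
                        gxp[:, :, i:i + stride * OH:stride,
                            j:j + stride * OW:stride] += gij.transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:padding + H, padding:padding + W]
                self._accum(gxp)

        return self._make(out, (self, weight) + (() if bias is None else (bias,)),
                          backward)

    def maxpool2d(self, kernel: int = 2, stride: int = 2) -> "Tensor":
        x = self.data
        B, C, H, W = x.shape
        OH = (H - kernel) // stride + 1
        OW = (W - kernel) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(2, 3))
        win = win[:, :, ::stride, ::stride].reshape(B, C, OH, OW, kernel * kernel)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def backward(g: np.ndarray) -> None:
            gx = np.zeros_like(x)
            ky, kx_ = np.divmod(idx, kernel)
            oy = np.arange(OH)[None, None, :, None] * stride
            ox = np.arange(OW)[None, None, None, :] * stride
            rows = (oy + ky).ravel()
            colz = (ox + kx_).ravel()
            bb = np.repeat(np.arange(B), C * OH * OW)
            cc = np.tile(np.repeat(np.arange(C), OH * OW), B)
            np.add.at(gx, (bb, cc, rows, colz), g.ravel())
            self._accum(gx)

        return self._make(np.ascontiguousarray(out), (self,), backward)

    def upsample_nearest2x(self) -> "Tensor":
        out = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g: np.ndarray) -> None:
            B, C, H2, W2 = g.shape
            gr = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            self._accum(gr)

        return self._make(out, (self,), backward)

    def batchnorm(self, gamma: "Tensor", beta: "Tensor",
                  running_mean: np.ndarray | None = None,
                  running_var: np.ndarray | None = None,
                  training: bool = True, momentum: float = 0.1,
                  eps: float = 1e-5) -> "Tensor":
        """Per-channel batch normalisation for [B,C,H,W] (or [B,C]) input.

        Fused primitive with the standard analytic backward pass.  When
        ``training`` and running buffers are given, they are updated in place.
        """
        x = self.data
        axes = (0,) if x.ndim == 2 else (0, 2, 3)
        shape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if running_mean is not None:
                running_mean *= 1.0 - momentum
                running_mean += momentum * mu
                running_var *= 1.0 - momentum
                running_var += momentum * var
        else:
            mu = running_mean
            var = running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
        n = x.size // x.shape[1]

        def backward(g: np.ndarray) -> None:
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gxhat = g * gamma.data.reshape(shape)
                if training:
                    gx = (inv.reshape(shape) / n) * (
                        n * gxhat
                        - gxhat.sum(axis=axes, keepdims=True)
                        - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
                    )
                else:
                    gx = gxhat * inv.reshape(shape)
                self._accum(gx)

        return self._make(out, (self, gamma, beta), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))
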