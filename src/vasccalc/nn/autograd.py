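"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; ``backward()`` walks the tape in reverse topological order.  Only the
operations needed by the segmentation network and its loss are provided:
elementwise arithmetic with broadcasting, relu/sigmoid/log/clamp,
reductions, channel concatenation, 2-D convolution, batch normalisation
and nearest-neighbour ×2 upsampling.  All computation is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other).reciprocal()

    def __rtruediv__(self, other):
        return self._lift(other) * self.reciprocal()

    def reciprocal(self):
        out = Tensor(1.0 / self.data, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(-out.grad / (self.data * self.data))

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bw
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        inside = (self.data > lo) & (self.data < hi)

        def bw():
            if self.requires_grad:
                self._accum(out.grad * inside)

        out._backward = bw
        return out

    # -- reductions and shaping --------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))

        out._backward = bw
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(g)

        out._backward = bw
        return out

    # -- structured ops ----------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, padding: int = 1):
        """2-D convolution, NCHW layout, square kernel, symmetric padding."""
        x = self.data
        w = weight.data  # (F, C, kh, kw)
        n, c, h, ww_ = x.shape
        f, _, kh, kw = w.shape
        oh = (h + 2 * padding - kh) // stride + 1
        ow = (ww_ + 2 * padding - kw) // stride + 1
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
        wmat = w.reshape(f, c * kh * kw)
        out_data = (cols @ wmat.T + bias.data.reshape(1, 1, f)).transpose(0, 2, 1)
        out = Tensor(out_data.reshape(n, f, oh, ow), _prev=(self, weight, bias))

        def bw():
            g = out.grad.reshape(n, f, oh * ow).transpose(0, 2, 1)  # (N, OH*OW, F)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                dw = np.einsum("npf,npk->fk", g, cols, optimize=True)
                weight._accum(dw.reshape(w.shape))
            if self.requires_grad:
                dcols = g @ wmat  # (N, OH*OW, C*kh*kw)
                dcols = dcols.reshape(n, oh, ow, c, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accum(dxp)

        out._backward = bw
        return out

    def batchnorm2d(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ):
        """Batch normalisation over (N, H, W) per channel.

        In training mode batch statistics are used and the running buffers
        are updated in place; in eval mode the running buffers are used.
        """
        x = self.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mu, var = running_mean, running_var
        std = np.sqrt(var + eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        g4 = gamma.data[None, :, None, None]
        out = Tensor(xhat * g4 + beta.data[None, :, None, None], _prev=(self, gamma, beta))

        def bw():
            go = out.grad
            if beta.requires_grad:
                beta._accum(go.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
            if self.requires_grad:
                if training:
                    gh = go * g4  # dL/dxhat
                    mean_gh = gh.mean(axis=(0, 2, 3), keepdims=True)
                    mean_ghx = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    dx = (gh - mean_gh - xhat * mean_ghx) / std[None, :, None, None]
                else:
                    dx = go * g4 / std[None, :, None, None]
                self._accum(dx)

        out._backward = bw
        return out

    def upsample2x(self):
        """Nearest-neighbour ×2 spatial upsampling (NCHW)."""
        out = Tensor(self.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(self,))

        def bw():
            if self.requires_grad:
                n, c, h2, w2 = out.grad.shape
                g = out.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                self._accum(g)

        out._backward = bw
        return out
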