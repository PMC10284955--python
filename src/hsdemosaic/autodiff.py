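"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine provides exactly the operations needed to express the
demosaicking losses and the small convolutional backbones used for
training: elementwise arithmetic with broadcasting, reductions, basic
slicing, 2-D convolution (stride 1, symmetric zero padding), 2×2 average
pooling, nearest-neighbour ×2 upsampling, channel concatenation and
matrix multiplication.

Design notes
------------
* A :class:`Tensor` wraps a float numpy array. Operations build a DAG;
  :meth:`Tensor.backward` runs a topological sweep accumulating
  gradients into ``.grad`` of every tensor with ``requires_grad=True``.
* Gradients propagate through any tensor that has a gradient-requiring
  ancestor, so constants cost nothing.
* dtype follows the input arrays (float32 for training speed, float64
  for numerically tight tests); mixed inputs promote via numpy rules.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def _needs_graph(self) -> bool:
        return self.requires_grad or self._parents != ()

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p._needs_graph() for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        o = self._lift(other)

        def bw(g, a=self, b=o):
            if a._needs_graph():
                a._accum(_unbroadcast(g, a.shape))
            if b._needs_graph():
                b._accum(_unbroadcast(g, b.shape))

        return self._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __mul__(self, other):
        o = self._lift(other)

        def bw(g, a=self, b=o):
            if a._needs_graph():
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b._needs_graph():
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g, a=self):
            if a._needs_graph():
                a._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        o = self._lift(other)

        def bw(g, a=self, b=o):
            if a._needs_graph():
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b._needs_graph():
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g, a=self):
            if a._needs_graph():
                a._accum(g * e * a.data ** (e - 1.0))

        return self._make(self.data**e, (self,), bw)

    def __abs__(self):
        def bw(g, a=self):
            if a._needs_graph():
                a._accum(g * np.sign(a.data))

        return self._make(np.abs(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, od=out_data):
            if a._needs_graph():
                # guard the derivative at 0 (subgradient 0 keeps descent finite)
                denom = np.where(od > 0, 2.0 * od, np.inf)
                a._accum(g / denom)

        return self._make(out_data, (self,), bw)

    def relu(self):
        def bw(g, a=self):
            if a._needs_graph():
                a._accum(g * (a.data > 0))

        return self._make(np.maximum(self.data, 0), (self,), bw)

    def leaky_relu(self, slope: float = 0.1):
        def bw(g, a=self, s=slope):
            if a._needs_graph():
                a._accum(g * np.where(a.data > 0, 1.0, s))

        return self._make(np.where(self.data > 0, self.data, slope * self.data), (self,), bw)

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self, ax=axis, kd=keepdims):
            if a._needs_graph():
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            if a._needs_graph():
                a._accum(g.reshape(a.shape))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, a=self, inv=inv):
            if a._needs_graph():
                a._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g, a=self, idx=idx):
            if a._needs_graph():
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(self.data[idx], (self,), bw)

    def __matmul__(self, other):
        o = self._lift(other)

        def bw(g, a=self, b=o):
            if a._needs_graph():
                a._accum(g @ b.data.T)
            if b._needs_graph():
                b._accum(a.data.T @ g)

        return self._make(self.data @ o.data, (self, o), bw)

    # -- neural-net ops -------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int | None = None):
        """2-D convolution (cross-correlation), stride 1.

        ``self``: (N, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,).
        ``padding`` defaults to "same" for odd kernels.
        """
        w = self._lift(weight)
        x = self
        kh, kw = w.shape[2], w.shape[3]
        p = (kh // 2) if padding is None else int(padding)
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H',W',kh,kw)
        out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # (N,H',W',O)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        parents = (x, w) if bias is None else (x, w, bias)

        def bw(g, x=x, w=w, b=bias, win=win, p=p, kh=kh, kw=kw):
            if b is not None and b._needs_graph():
                b._accum(g.sum(axis=(0, 2, 3)))
            if w._needs_graph():
                # (N,O,H,W) x (N,C,H,W,kh,kw) -> (O,C,kh,kw)
                gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
                w._accum(gw)
            if x._needs_graph():
                q = kh - 1 - p
                gp = np.pad(g, ((0, 0), (0, 0), (q, q), (kw - 1 - p, kw - 1 - p)))
                wf = w.data[:, :, ::-1, ::-1]
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))  # (N,O,H,W,kh,kw)
                gx = np.tensordot(gwin, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,C)
                x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

        return self._make(out, parents, bw)

    def avg_pool2(self):
        """2×2 average pooling on (N, C, H, W); H, W must be even."""
        n, c, h, w = self.shape
        out = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def bw(g, a=self):
            if a._needs_graph():
                up = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
                a._accum(up)

        return self._make(out, (self,), bw)

    def upsample2(self):
        """Nearest-neighbour ×2 upsampling on (N, C, H, W)."""
        out = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)

        def bw(g, a=self):
            if a._needs_graph():
                n, c, h, w = a.shape
                a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return self._make(out, (self,), bw)

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p._needs_graph():
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t._needs_graph():
                idx = [slice(None)] * g.ndim
                idx[ax] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t._needs_graph() for t in tensors):
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def as_tensor(x) -> Tensor:
    """Wrap an array (or Tensor) as a constant Tensor."""
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))
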