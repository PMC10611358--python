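"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` replays them in reverse topological order.
Only the operations the EEG classifiers need are implemented: broadcasting
arithmetic, matmul, reductions, shape ops, slicing/concatenation, the
activation functions, a stride-1 1-D convolution and non-overlapping max
pooling. Convolution is evaluated as an im2col matrix product so the heavy
lifting stays inside BLAS.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "no_grad", "concatenate", "conv1d", "maxpool1d"]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph recording (evaluation mode) within the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _grad_on() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_on() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        g = g.astype(np.float32, copy=False)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs include per-timestep LSTM nodes
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = _wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = g @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g)
                else:
                    gb = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def gelu(self):
        """Gaussian error linear unit x * Phi(x), tanh approximation
        (max deviation from the exact erf form ~1e-3, standard practice)."""
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        a = np.float32(0.044715)
        x2 = x * x
        t = np.tanh(c * (x + a * x2 * x))
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            # d/dx [0.5 x (1 + tanh(u))] with u = c (x + a x^3)
            du = c * (1.0 + 3.0 * a * x2)
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du))

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accum(g.swapaxes(a, b))

        return Tensor._make(self.data.swapaxes(a, b), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accum(gx)

        return Tensor._make(out_data, (self,), bw)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, valid-mode 1-D convolution (cross-correlation).

    ``x``: (batch, in_channels, length); ``w``: (out_channels, in_channels, k);
    output: (batch, out_channels, length - k + 1).
    """
    xd, wd = x.data, w.data
    B, C, L = xd.shape
    O, C2, K = wd.shape
    if C != C2:
        raise ValueError(f"conv1d channel mismatch: input has {C}, kernel expects {C2}")
    if K > L:
        raise ValueError(f"kernel size {K} exceeds input length {L}")
    Lo = L - K + 1
    windows = np.lib.stride_tricks.sliding_window_view(xd, K, axis=2)  # (B,C,Lo,K)
    cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(B * Lo, C * K)
    out = cols @ wd.reshape(O, C * K).T
    out = out.reshape(B, Lo, O).transpose(0, 2, 1)
    if b is not None:
        out = out + b.data[None, :, None]

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lo, O)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(O, C, K))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = gmat @ wd.reshape(O, C * K)
            gwin = gcols.reshape(B, Lo, C, K).transpose(0, 2, 1, 3)
            gx = np.zeros_like(xd)
            for k in range(K):
                gx[:, :, k : k + Lo] += gwin[:, :, :, k]
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(np.ascontiguousarray(out), parents, bw)


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling along the last axis (stride = window = k)."""
    xd = x.data
    B, C, L = xd.shape
    Lg = L // k
    if Lg < 1:
        raise ValueError(f"pool window {k} exceeds input length {L}")
    L2 = Lg * k
    xr = xd[:, :, :L2].reshape(B, C, Lg, k)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def bw(g):
        gr = np.zeros((B, C, Lg, k), dtype=xd.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=3)
        gx = np.zeros_like(xd)
        gx[:, :, :L2] = gr.reshape(B, C, L2)
        x._accum(gx)

    return Tensor._make(out, (x,), bw)
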