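"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations a 2-D encoder–decoder segmentation network
needs: padded convolution, 2x2 transposed convolution, 2x2 max pooling,
instance normalization, leaky ReLU / sigmoid, channel concatenation, and the
elementwise / reduction primitives losses are built from.  Gradients are
accumulated by topological traversal of the tape recorded during the forward
pass.  Arrays keep the dtype they were created with (layers use float32;
gradient-check tests use float64).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "instance_norm2d",
    "leaky_relu",
    "sigmoid",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (used for teacher-model inference)."""
    global _GRAD_ENABLED
    old, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction of non-leaf nodes ---------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Iterable["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- public API ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for stacked conv nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        data = self.data + o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.shape))

        return Tensor._result(data, (self, o), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        return self + (-o)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        data = self.data * o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.shape))

        return Tensor._result(data, (self, o), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        data = self.data / o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data * o.data), o.shape))

        return Tensor._result(data, (self, o), backward)

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._result(data, (self,), backward)

    # -- nonlinearities & reductions -------------------------------------
    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._result(data, (self,), backward)

    def clip(self, lo: float, hi: float):
        data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(data, (self,), backward)

    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape).astype(self.dtype))

        return Tensor._result(np.asarray(self.data.sum(), dtype=self.dtype), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.shape).astype(self.dtype))

        return Tensor._result(np.asarray(self.data.mean(), dtype=self.dtype), (self,), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    x = _as_tensor(x)
    pos = x.data > 0
    data = np.where(pos, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(np.where(pos, g, slope * g))

    return Tensor._result(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    # numerically stable two-sided form
    data = np.where(x.data >= 0,
                    1.0 / (1.0 + np.exp(-np.abs(x.data))),
                    np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    data = data.astype(x.dtype)

    def backward(g):
        if x.requires_grad:
            x._accum(g * data * (1.0 - data))

    return Tensor._result(data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._result(data, tensors, backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int = 0) -> Tensor:
    """NCHW convolution, stride 1, square kernel, via im2col + one GEMM."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    B, C, H, W = x.shape
    O, C2, K, _ = weight.shape
    if C != C2:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {C2}")
    p = padding
    Ho, Wo = H + 2 * p - K + 1, W + 2 * p - K + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    # (B, C, Ho, Wo, K, K) windows -> (C*K*K, B*Ho*Wo) matrix
    windows = np.lib.stride_tricks.sliding_window_view(xp, (K, K), axis=(2, 3))
    cols = np.ascontiguousarray(windows.transpose(1, 4, 5, 0, 2, 3)
                                ).reshape(C * K * K, B * Ho * Wo)
    wmat = weight.data.reshape(O, C * K * K)
    out = (wmat @ cols).reshape(O, B, Ho, Wo).transpose(1, 0, 2, 3)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(O, B * Ho * Wo)
        if x.requires_grad:
            dcols = (wmat.T @ gmat).reshape(C, K, K, B, Ho, Wo)
            gxp = np.zeros_like(xp)
            for di in range(K):
                for dj in range(K):
                    gxp[:, :, di:di + Ho, dj:dj + Wo] += dcols[:, di, dj].transpose(1, 0, 2, 3)
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)
        if weight.requires_grad:
            weight._accum((gmat @ cols.T).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return Tensor._result(np.ascontiguousarray(out), parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2x2 stride-2 transposed convolution; weight shape (Cin, Cout, 2, 2)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    B, C, H, W = x.shape
    C2, O, K, _ = weight.shape
    if C != C2:
        raise ValueError(f"conv_transpose2d: input has {C} channels, weight expects {C2}")
    xmat = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)).reshape(C, B * H * W)
    # all 4 kernel taps in one GEMM: (4*O, C) @ (C, BHW)
    wmat = weight.data.transpose(2, 3, 1, 0).reshape(4 * O, C)
    taps = (wmat @ xmat).reshape(2, 2, O, B, H, W)
    out = np.zeros((B, O, 2 * H, 2 * W), dtype=x.dtype)
    for di in range(2):
        for dj in range(2):
            out[:, :, di::2, dj::2] = taps[di, dj].transpose(1, 0, 2, 3)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        gt = np.stack([np.ascontiguousarray(
            g[:, :, di::2, dj::2].transpose(1, 0, 2, 3)).reshape(O, B * H * W)
            for di in range(2) for dj in range(2)])  # (4, O, BHW)
        gtm = gt.reshape(4 * O, B * H * W)
        if x.requires_grad:
            gx = (wmat.T @ gtm).reshape(C, B, H, W).transpose(1, 0, 2, 3)
            x._accum(np.ascontiguousarray(gx))
        if weight.requires_grad:
            gw = (gtm @ xmat.T).reshape(2, 2, O, C).transpose(3, 2, 0, 1)
            weight._accum(np.ascontiguousarray(gw))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return Tensor._result(out, parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; rejects odd spatial dimensions."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d: odd spatial dimensions ({H}, {W})")
    windows = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(B, C, H // 2, W // 2, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gw = np.zeros_like(windows)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gw = gw.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gw.reshape(B, C, H, W))

    return Tensor._result(out, (x,), backward)


def instance_norm2d(x: Tensor, gamma: Tensor | None, beta: Tensor | None,
                    eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial plane."""
    x = _as_tensor(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat
    if gamma is not None:
        out = out * gamma.data[None, :, None, None]
    if beta is not None:
        out = out + beta.data[None, :, None, None]

    def backward(g):
        gh = g * gamma.data[None, :, None, None] if gamma is not None else g
        if x.requires_grad:
            m1 = gh.mean(axis=(2, 3), keepdims=True)
            m2 = (gh * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum(inv * (gh - m1 - xhat * m2))
        if gamma is not None and gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta is not None and beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))

    parents = tuple(t for t in (x, gamma, beta) if t is not None)
    return Tensor._result(out.astype(x.dtype), parents, backward)
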