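"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the sequence models live here: broadcasted
elementwise arithmetic, (batched) matrix products, dilated 1-D convolution,
reductions, softmax and a fused softmax cross-entropy.  Gradients are
verified against central finite differences in the test suite.
"""
from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[Tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- graph construction --------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], Callable[[], None]]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward(out)
        return out

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _coerce(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: ArrayLike) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(out: Tensor):
            def fn():
                self._accumulate(_unbroadcast(out.grad, self.shape))
                other._accumulate(_unbroadcast(out.grad, other.shape))
            return fn
        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(out: Tensor):
            def fn():
                self._accumulate(-out.grad)
            return fn
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(out: Tensor):
            def fn():
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            return fn
        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = Tensor._coerce(other)
        return self * other.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        def bw(out: Tensor):
            def fn():
                self._accumulate(
                    out.grad * exponent * self.data ** (exponent - 1.0)
                )
            return fn
        return Tensor._make(self.data ** exponent, (self,), bw)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape

        def bw(out: Tensor):
            def fn():
                self._accumulate(out.grad.reshape(old))
            return fn
        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bw(out: Tensor):
            def fn():
                self._accumulate(out.grad.swapaxes(a, b))
            return fn
        return Tensor._make(self.data.swapaxes(a, b), (self,), bw)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(out: Tensor):
            def fn():
                g = out.grad
                if axis is not None and not keepdims:
                    axes = (axis,) if isinstance(axis, int) else tuple(axis)
                    for ax in sorted(a % self.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            return fn
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(out: Tensor):
            def fn():
                self._accumulate(out.grad * mask)
            return fn
        return Tensor._make(self.data * mask, (self,), bw)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def bw(out: Tensor):
            def fn():
                self._accumulate(out.grad * (1.0 - y * y))
            return fn
        return Tensor._make(y, (self,), bw)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bw(out: Tensor):
            def fn():
                self._accumulate(out.grad * y * (1.0 - y))
            return fn
        return Tensor._make(y, (self,), bw)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._coerce(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires tensors of rank >= 2")

        def bw(out: Tensor):
            def fn():
                g = out.grad
                self._accumulate(
                    _unbroadcast(np.matmul(g, other.data.swapaxes(-1, -2)), self.shape)
                )
                other._accumulate(
                    _unbroadcast(np.matmul(self.data.swapaxes(-1, -2), g), other.shape)
                )
            return fn
        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(out: Tensor):
        def fn():
            g = out.grad
            x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))
        return fn
    return Tensor._make(y, (x,), bw)


def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           dilation: int = 1, pad_left: int = 0, pad_right: int = 0) -> Tensor:
    """Dilated 1-D convolution (cross-correlation) with explicit padding.

    ``x`` is (batch, c_in, T), ``w`` is (c_out, c_in, k), ``b`` is (c_out,).
    Output length is T + pad_left + pad_right - dilation*(k-1).
    """
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    B, c_in, T = x.shape
    c_out, c_in_w, k = w.shape
    if c_in_w != c_in:
        raise ValueError(f"weight expects {c_in_w} input channels, got {c_in}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    t_out = T + pad_left + pad_right - dilation * (k - 1)
    if t_out < 1:
        raise ValueError("output length would be < 1")
    gather = np.arange(t_out)[:, None] + dilation * np.arange(k)[None, :]
    patches = xp[:, :, gather]  # (B, c_in, t_out, k)
    y = np.einsum("bctk,ock->bot", patches, w.data, optimize=True)
    if b is not None:
        y = y + b.data[:, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(out: Tensor):
        def fn():
            g = out.grad  # (B, c_out, t_out)
            w._accumulate(np.einsum("bot,bctk->ock", g, patches, optimize=True))
            if b is not None:
                b._accumulate(g.sum(axis=(0, 2)))
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j * dilation:j * dilation + t_out] += np.einsum(
                    "bot,oc->bct", g, w.data[:, :, j], optimize=True
                )
            end = xp.shape[2] - pad_right
            x._accumulate(gxp[:, :, pad_left:end])
        return fn
    return Tensor._make(y, parents, bw)


def avg_pool1d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling along the last axis; the tail is cropped."""
    if factor < 1:
        raise ValueError("pool factor must be >= 1")
    B, C, T = x.shape
    t_out = T // factor
    if t_out < 1:
        raise ValueError("sequence shorter than the pool factor")
    cropped = x.data[:, :, : t_out * factor].reshape(B, C, t_out, factor)
    y = cropped.mean(axis=-1)

    def bw(out: Tensor):
        def fn():
            g = np.zeros_like(x.data)
            g[:, :, : t_out * factor] = np.repeat(out.grad, factor, axis=-1) / factor
            x._accumulate(g)
        return fn
    return Tensor._make(y, (x,), bw)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer class targets."""
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), targets].mean()

    def bw(out: Tensor):
        def fn():
            p = np.exp(logp)
            p[np.arange(n), targets] -= 1.0
            logits._accumulate(p * (out.grad / n))
        return fn
    return Tensor._make(np.asarray(loss), (logits,), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; caller decides whether training mode is active."""
    if not 0.0 <= p < 1.0:
        raise ValueError("dropout probability must be in [0, 1)")
    if p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
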