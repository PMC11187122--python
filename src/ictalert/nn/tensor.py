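"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the operator set needed by the seizure
prediction models (1-D convolutions, batch normalisation, LSTM cells,
dense layers and the usual elementwise nonlinearities).  It is not a
general deep-learning framework: shapes follow the ``(batch, channels,
time)`` convention used throughout the package and only the indexing
patterns the layers use are supported.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  A node is
only differentiated if ``requires_grad`` propagated to it, so frozen
subgraphs (e.g. a transferred encoder) cost no backward work.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "mean",
    "mse_loss",
    "sigmoid",
    "lstm_last",
    "softmax",
    "softmax_cross_entropy",
    "swish",
    "tanh",
    "upsample1d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _ensure_grad(self) -> np.ndarray:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        self._ensure_grad()
        self.grad = self.grad + np.asarray(grad, dtype=self.data.dtype)

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
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other._ensure_grad()
                other.grad += _unbroadcast(g, other.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += -g

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other._ensure_grad()
                other.grad += _unbroadcast(g * self.data, other.shape)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += g * exponent * self.data ** (exponent - 1.0)

        out._backward = backward
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += g @ other.data.T
            if other.requires_grad:
                other._ensure_grad()
                other.grad += self.data.T @ g

        out._backward = backward
        return out

    # -- shape ops -------------------------------------------------------
    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice)) for p in parts)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                if basic:
                    self.grad[idx] += g
                else:
                    np.add.at(self.grad, idx, g)

        out._backward = backward
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += g.reshape(self.shape)

        out._backward = backward
        return out

    def transpose(self, *axes: int) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._ensure_grad()
                self.grad += g.transpose(*inv)

        out._backward = backward
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            self._ensure_grad()
            if axis is None:
                self.grad += g * np.ones_like(self.data)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                self.grad += np.broadcast_to(g, self.shape)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


# ---------------------------------------------------------------------------
# free functions


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    return x.mean(axis=axis, keepdims=keepdims)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._ensure_grad()
            x.grad += g * s * (1.0 - s)

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, x.requires_grad, (x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._ensure_grad()
            x.grad += g * (1.0 - t * t)

    out._backward = backward
    return out


def swish(x: Tensor) -> Tensor:
    """Swish activation x * sigmoid(x)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * s, x.requires_grad, (x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._ensure_grad()
            x.grad += g * (s + x.data * s * (1.0 - s))

    out._backward = backward
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._ensure_grad()
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D convolution.

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    Output length is ``(L + 2*pad - K) // stride + 1``.
    """
    O, C, K = w.shape
    N, _, L = x.shape
    Xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lp = Xp.shape[2]
    T = (Lp - K) // stride + 1
    span = (T - 1) * stride + 1
    # one batched GEMM per kernel tap: avoids materialising the K-fold
    # im2col expansion, which is memory-bound at these shapes
    out_data = np.zeros((N, O, T), dtype=np.result_type(x.data, w.data))
    for k in range(K):
        out_data += np.matmul(w.data[:, :, k][None], Xp[:, :, k : k + span : stride])
    out_data += b.data[None, :, None]
    out = Tensor(
        out_data,
        x.requires_grad or w.requires_grad or b.requires_grad,
        (x, w, b),
    )

    def backward(g: np.ndarray) -> None:
        if w.requires_grad:
            w._ensure_grad()
            for k in range(K):
                w.grad[:, :, k] += np.tensordot(
                    g, Xp[:, :, k : k + span : stride], axes=([0, 2], [0, 2])
                )
        if b.requires_grad:
            b._ensure_grad()
            b.grad += g.sum(axis=(0, 2))
        if x.requires_grad:
            x._ensure_grad()
            gXp = np.zeros_like(Xp)
            for k in range(K):
                gXp[:, :, k : k + span : stride] += np.matmul(w.data[:, :, k].T[None], g)
            x.grad += gXp[:, :, pad : Lp - pad] if pad else gXp

    out._backward = backward
    return out


def upsample1d(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour temporal upsampling of (N, C, T) by ``factor``."""
    out = Tensor(np.repeat(x.data, factor, axis=2), x.requires_grad, (x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._ensure_grad()
            n, c, t = x.shape
            x.grad += g.reshape(n, c, t, factor).sum(axis=3)

    out._backward = backward
    return out


def lstm_last(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor, reverse: bool = False) -> Tensor:
    """Final hidden state of an LSTM over the time axis of (N, C, T).

    Gate layout in the 4H projection is [input, forget, cell, output].
    Forward and the full backward-through-time pass are fused into one
    graph node: the recurrence is too fine-grained to leave to the
    per-operator autodiff.
    """
    N, C, T = x.shape
    H = wh.shape[0]
    dtype = np.result_type(x.data, wx.data)
    # batched input projection for all timesteps
    xt = np.ascontiguousarray(x.data.transpose(0, 2, 1)).reshape(N * T, C)
    ZX = (xt @ wx.data).reshape(N, T, 4 * H) + b.data
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((N, H), dtype=dtype)
    c = np.zeros((N, H), dtype=dtype)
    cache = []
    for t in order:
        z = ZX[:, t] + h @ wh.data
        i = 1.0 / (1.0 + np.exp(-z[:, 0:H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H : 4 * H]))
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        cache.append((t, i, f, g, o, c_prev, h_prev, tc))
    out = Tensor(
        h,
        x.requires_grad or wx.requires_grad or wh.requires_grad or b.requires_grad,
        (x, wx, wh, b),
    )

    def backward(dh_out: np.ndarray) -> None:
        dZX = np.zeros_like(ZX)
        dWh = np.zeros_like(wh.data)
        dh = dh_out.astype(dtype)
        dc = np.zeros((N, H), dtype=dtype)
        for (t, i, f, g, o, c_prev, h_prev, tc) in reversed(cache):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dZX[:, t] = dz
            dWh += h_prev.T @ dz
            dh = dz @ wh.data.T
            dc = dc * f
        dZX2 = dZX.reshape(N * T, 4 * H)
        if b.requires_grad:
            b._ensure_grad()
            b.grad += dZX2.sum(axis=0)
        if wh.requires_grad:
            wh._ensure_grad()
            wh.grad += dWh
        if wx.requires_grad:
            wx._ensure_grad()
            wx.grad += xt.T @ dZX2
        if x.requires_grad:
            x._ensure_grad()
            dx = (dZX2 @ wx.data.T).reshape(N, T, C).transpose(0, 2, 1)
            x.grad += dx

    out._backward = backward
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on a plain array (inference path)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Fused forward/backward for numerical stability; for two classes this is
    binary cross-entropy on the softmax output.
    """
    n = logits.shape[0]
    p = softmax(logits.data, axis=1)
    eps = np.finfo(p.dtype).tiny
    nll = -np.log(p[np.arange(n), labels] + eps)
    out = Tensor(np.asarray(nll.mean(), dtype=logits.data.dtype), logits.requires_grad, (logits,))

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            logits._ensure_grad()
            delta = p.copy()
            delta[np.arange(n), labels] -= 1.0
            logits.grad += g * delta / n

    out._backward = backward
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    diff = pred.data - target
    out = Tensor(np.asarray(np.mean(diff ** 2), dtype=pred.data.dtype), pred.requires_grad, (pred,))

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._ensure_grad()
            pred.grad += g * 2.0 * diff / diff.size

    out._backward = backward
    return out
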