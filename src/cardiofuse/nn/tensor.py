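"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small define-by-run engine: :class:`Tensor` wraps an
``ndarray`` and records a backward closure per operation.  Only the
operations the fusion network needs are provided (1-D convolution, batch
normalization, pooling, dense layers, elementwise gates, concatenation,
slicing, dropout and a fused weighted softmax cross-entropy).

Float32 is the working precision; tests that compare against finite
differences switch to float64 via :func:`set_default_dtype`.
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_DEFAULT_DTYPE = np.float32
_GRAD_ENABLED = True


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=dtype or _DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here are deep
            node, processed = stack.pop()
            if processed:
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
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data.item() if self.data.ndim else self.data)


def _result(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out.requires_grad = needs
    if needs:
        out._parents = tuple(parents)
        out._backward = backward
    else:
        out._parents = ()
        out._backward = None
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` back down to ``shape`` (inverse of broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def astensor(x, dtype=None) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, dtype=dtype)


# ---------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _result(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _result(data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return _result(data, (a,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _result(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    s = expit(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return _result(s, (x,), backward)


# ---------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _result(data, tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries starting at ``start`` along ``axis``."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accumulate(full)

    return _result(data, (x,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    return _result(data, (x,), backward)


def mean_channels(x: Tensor) -> Tensor:
    """Mean over the channel axis of an (N, C, L) tensor, keepdims."""
    c = x.data.shape[1]
    data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / c, x.data.shape))

    return _result(data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, L) -> (N, C) mean over the length axis."""
    L = x.data.shape[2]
    data = x.data.mean(axis=2)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.repeat(g[:, :, None], L, axis=2) / L)

    return _result(data, (x,), backward)


def avg_pool1d(x: Tensor, window: int) -> Tensor:
    """Non-overlapping average pooling (stride == window) on (N, C, L)."""
    n, c, L = x.data.shape
    if L % window:
        raise ValueError(
            f"avg_pool1d: length {L} not divisible by window {window}"
        )
    data = x.data.reshape(n, c, L // window, window).mean(axis=3)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.repeat(g, window, axis=2) / window)

    return _result(data, (x,), backward)


def expand_channels(x: Tensor, channels: int) -> Tensor:
    """Broadcast an (N, 1, L) tensor to (N, channels, L)."""
    data = np.broadcast_to(x.data, (x.data.shape[0], channels, x.data.shape[2]))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.sum(axis=1, keepdims=True))

    return _result(np.ascontiguousarray(data), (x,), backward)


# ---------------------------------------------------------------------
# dense / conv / norm
# ---------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    data = x.data @ w.data
    if b is not None:
        data = data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _result(data, parents, backward)


def same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    """TF-style SAME padding: output length ceil(L / stride)."""
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: tuple[int, int] | None = None) -> Tensor:
    """1-D convolution (cross-correlation) on (N, C, L) with weight (O, C, K)."""
    n, c, L = x.data.shape
    o, c2, k = w.data.shape
    if c != c2:
        raise ValueError(f"conv1d: input has {c} channels, weight expects {c2}")
    if padding is None:
        padding = same_pad(L, k, stride)
    pl, pr = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x.data
    win = sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]
    data = np.einsum("nclk,ock->nol", win, w.data, optimize=True)
    if b is not None:
        data += b.data[None, :, None]
    lout = data.shape[2]

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nol,nclk->ock", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for kk in range(k):
                end = kk + stride * (lout - 1) + 1
                dxp[:, :, kk:end:stride] += np.einsum(
                    "nol,oc->ncl", g, w.data[:, :, kk], optimize=True
                )
            x._accumulate(dxp[:, :, pl:pl + L] if (pl or pr) else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _result(data, parents, backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, L) per channel of an (N, C, L) tensor.

    ``running_mean``/``running_var`` are updated in place in training mode.
    """
    if training:
        mean = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None]) * inv_std[None, :, None]
    data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            if training:
                m = x.data.shape[0] * x.data.shape[2]
                gmean = g.mean(axis=(0, 2))[None, :, None]
                gxhat = (g * xhat).mean(axis=(0, 2))[None, :, None]
                dx = (gamma.data * inv_std)[None, :, None] * (
                    g - gmean - xhat * gxhat
                )
            else:
                dx = (gamma.data * inv_std)[None, :, None] * g
            x._accumulate(dx)

    return _result(data, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    keep = keep.astype(x.data.dtype)
    data = x.data * keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return _result(data, (x,), backward)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean cross-entropy over a batch of integer targets.

    The mean is taken over the sum of sample weights, so per-class weights
    that average to one on a balanced batch leave the loss unchanged.
    """
    n = logits.data.shape[0]
    targets = np.asarray(targets, dtype=np.intp)
    logp = log_softmax(logits.data)
    if class_weights is None:
        sw = np.ones(n, dtype=logits.data.dtype)
    else:
        sw = np.asarray(class_weights, dtype=logits.data.dtype)[targets]
    denom = sw.sum()
    loss = -(sw * logp[np.arange(n), targets]).sum() / denom

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), targets] -= 1.0
            logits._accumulate(g * p * (sw / denom)[:, None])

    return _result(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))
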