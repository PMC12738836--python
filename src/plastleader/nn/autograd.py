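"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based autodiff core sized for 1-D sequence models: dense and
batched matrix products, same-length 1-D convolution, batch normalisation,
max-pooling, the usual pointwise nonlinearities, and shape surgery
(slice/concat/stack/transpose). Everything is float32. Gradients flow only
through :class:`Tensor` objects with ``requires_grad=True``; wrap inference
code in :func:`no_grad` to skip taping.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate ``grad`` (default: ones) from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for p, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not p.requires_grad:
                    continue
                g = np.asarray(g, dtype=np.float32)
                p.grad = g if p.grad is None else p.grad + g

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- arithmetic --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _node(out, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        if b.ndim == 1:
            ga = np.outer(g, b.data) if a.ndim > 1 else g * b.data
            gb = a.data.T @ g if a.ndim > 1 else a.data * g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(out, (a, b), backward)


# -- pointwise ---------------------------------------------------------

def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _node(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    return _node(y, (x,), lambda g: (g * y * (1.0 - y),))


def tanh(x) -> Tensor:
    x = as_tensor(x)
    y = np.tanh(x.data)
    return _node(y, (x,), lambda g: (g * (1.0 - y * y),))


def exp(x) -> Tensor:
    x = as_tensor(x)
    y = np.exp(x.data)
    return _node(y, (x,), lambda g: (g * y,))


def log(x) -> Tensor:
    x = as_tensor(x)
    return _node(np.log(x.data), (x,), lambda g: (g / x.data,))


# -- reductions and shape ----------------------------------------------

def tsum(x, axis=None, keepdims=False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.shape).copy(),)

    return _node(out, (x,), backward)


def tmean(x, axis=None, keepdims=False) -> Tensor:
    x = as_tensor(x)
    if axis is None:
        n = x.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([x.shape[a] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    out = x.data.reshape(shape)
    return _node(out, (x,), lambda g: (g.reshape(x.shape),))


def transpose(x, axes) -> Tensor:
    x = as_tensor(x)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(x.data.transpose(axes), (x,), lambda g: (g.transpose(inv),))


def getitem(x, idx) -> Tensor:
    x = as_tensor(x)
    out = x.data[idx]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[idx] = g  # basic (slice/int) indexing: each element selected once
        return (gx,)

    return _node(out, (x,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(tensors), backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return _node(out, tuple(tensors), backward)


# -- composite / structured ops ----------------------------------------

def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return ((g - dot) * y,)

    return _node(y, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` given raw ``logits`` (n, k)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1)) + logits.data.max(axis=1)
    nll = logsumexp - logits.data[np.arange(n), labels]
    probs = np.exp(logits.data - logsumexp[:, None])

    def backward(g):
        gl = probs.copy()
        gl[np.arange(n), labels] -= 1.0
        return (gl * (g / n),)

    return _node(nll.mean(), (logits,), backward)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-length 1-D convolution, channels last.

    x: (n, L, c_in), w: (k, c_in, c_out), b: (c_out,) -> (n, L, c_out).
    ``k`` must be odd so that the symmetric zero-padding is exact.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, L, cin = x.shape
    k, _, cout = w.shape
    p = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (0, 0)))
    # windows[:, i, j, :] = xp[:, i + j, :]
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(n, L, k, cin), strides=(s[0], s[1], s[1], s[2])
    )
    wmat = w.data.reshape(k * cin, cout)
    out = win.reshape(n * L, k * cin) @ wmat + b.data
    out = out.reshape(n, L, cout)
    win_c = win.reshape(n * L, k * cin).copy()  # contiguous copy for backward

    def backward(g):
        gm = g.reshape(n * L, cout)
        gw = (win_c.T @ gm).reshape(k, cin, cout)
        gb = gm.sum(axis=0)
        gwin = (gm @ wmat.T).reshape(n, L, k, cin)
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[:, j : j + L, :] += gwin[:, :, j, :]
        return gxp[:, p : p + L, :], gw, gb

    return _node(out, (x, w, b), backward)


def max_pool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling along axis 1 of (n, L, c); truncates a ragged tail."""
    x = as_tensor(x)
    n, L, c = x.shape
    Lp = L // size
    xr = x.data[:, : Lp * size, :].reshape(n, Lp, size, c)
    idx = xr.argmax(axis=2)
    out = np.take_along_axis(xr, idx[:, :, None, :], axis=2).squeeze(2)

    def backward(g):
        gr = np.zeros((n, Lp, size, c), dtype=np.float32)
        np.put_along_axis(gr, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        gx[:, : Lp * size, :] = gr.reshape(n, Lp * size, c)
        return (gx,)

    return _node(out, (x,), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
                     eps: float = 1e-5):
    """Batch normalisation using batch statistics over ``axes``.

    Returns (out, batch_mean, batch_var) with the statistics as plain arrays
    so the caller can maintain running estimates.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = xhat * gamma.data + beta.data
    m = int(np.prod([x.shape[a] for a in axes]))

    def backward(g):
        dxhat = g * gamma.data
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        gx = inv_std * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        ggamma = _unbroadcast(g * xhat, gamma.shape)
        gbeta = _unbroadcast(g, beta.shape)
        return gx, ggamma, gbeta

    out_t = _node(out, (x, gamma, beta), backward)
    return out_t, np.squeeze(mu), np.squeeze(var) * m / max(m - 1, 1)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor):
    """Fused scaled dot-product attention.

    q, k, v: (n, heads, T, d_k). Returns (output, alpha) where alpha is the
    row-stochastic (n, heads, T, T) attention array (a plain ndarray, for
    inspection). Fusing keeps the T x T intermediates off the tape.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    d_k = q.shape[-1]
    scale = 1.0 / np.sqrt(d_k)
    scores = (q.data @ np.swapaxes(k.data, -1, -2)) * scale
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    alpha = scores  # (n, heads, T, T), rows sum to 1
    out = alpha @ v.data

    def backward(g):
        dv = np.swapaxes(alpha, -1, -2) @ g
        ds = g @ np.swapaxes(v.data, -1, -2)
        ds -= (ds * alpha).sum(axis=-1, keepdims=True)
        ds *= alpha  # softmax Jacobian applied in place
        dq = (ds @ k.data) * scale
        dk = (np.swapaxes(ds, -1, -2) @ q.data) * scale
        return dq, dk, dv

    return _node(out, (q, k, v), backward), alpha


def lstm_direction(x: Tensor, w_ih: Tensor, w_hh: Tensor, b: Tensor,
                   reverse: bool = False) -> Tensor:
    """One LSTM direction as a single fused op (truncated-nothing BPTT).

    x: (n, T, c_in); w_ih: (c_in, 4H); w_hh: (H, 4H); b: (4H,).
    Gate order (i, f, g, o). Returns hidden states (n, T, H) in time order
    regardless of direction. Fusing the whole scan into one tape node keeps
    the graph small and the backward pass cache-friendly.
    """
    x, w_ih, w_hh, b = as_tensor(x), as_tensor(w_ih), as_tensor(w_hh), as_tensor(b)
    n, T, _ = x.shape
    H = w_hh.shape[0]
    xw = x.data.reshape(n * T, -1) @ w_ih.data + b.data
    xw = xw.reshape(n, T, 4 * H)
    order = range(T - 1, -1, -1) if reverse else range(T)
    hs = np.zeros((n, T, H), dtype=np.float32)
    # caches for backward
    gi = np.empty((n, T, H), dtype=np.float32)
    gf = np.empty_like(gi)
    gg = np.empty_like(gi)
    go = np.empty_like(gi)
    cs = np.empty_like(gi)       # cell state after the step
    tanh_c = np.empty_like(gi)
    h_prev_all = np.empty_like(gi)
    c_prev_all = np.empty_like(gi)
    h = np.zeros((n, H), dtype=np.float32)
    c = np.zeros((n, H), dtype=np.float32)
    for t in order:
        h_prev_all[:, t] = h
        c_prev_all[:, t] = c
        pre = xw[:, t] + h @ w_hh.data
        i = 1.0 / (1.0 + np.exp(-pre[:, 0 * H:1 * H]))
        f = 1.0 / (1.0 + np.exp(-pre[:, 1 * H:2 * H]))
        g = np.tanh(pre[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-pre[:, 3 * H:4 * H]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gi[:, t], gf[:, t], gg[:, t], go[:, t] = i, f, g, o
        cs[:, t], tanh_c[:, t] = c, tc
        hs[:, t] = h

    def backward(gh):
        dxw = np.empty((n, T, 4 * H), dtype=np.float32)
        dw_hh = np.zeros_like(w_hh.data)
        dh_next = np.zeros((n, H), dtype=np.float32)
        dc_next = np.zeros((n, H), dtype=np.float32)
        for t in reversed(list(order)):
            i, f, g, o = gi[:, t], gf[:, t], gg[:, t], go[:, t]
            tc = tanh_c[:, t]
            dh = gh[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dgates = np.concatenate([
                dc * g * i * (1.0 - i),
                dc * c_prev_all[:, t] * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dxw[:, t] = dgates
            dw_hh += h_prev_all[:, t].T @ dgates
            dh_next = dgates @ w_hh.data.T
            dc_next = dc * f
        dxw2 = dxw.reshape(n * T, 4 * H)
        dw_ih = x.data.reshape(n * T, -1).T @ dxw2
        db = dxw2.sum(axis=0)
        dx = (dxw2 @ w_ih.data.T).reshape(x.shape)
        return dx, dw_ih, dw_hh, db

    return _node(hs, (x, w_ih, w_hh, b), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    x = as_tensor(x)
    if p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return _node(x.data * mask, (x,), lambda g: (g * mask,))
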