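"""Neural-network layers built on the autograd core.

Conventions: activations are channels-last, i.e. a batch of encoded
sequences is ``(n, L, channels)``. Parameter initialisation follows the
uniform fan-in scheme; every layer draws its initial weights from the
``numpy.random.Generator`` passed at construction so a model is a pure
function of its seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{key}.{i}.")
        for name in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{name}", getattr(self, name)

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.startswith("buffer:"):
                continue
            params[k].data = v.astype(np.float32).copy()
        buffer_owners = {k: (obj, name) for obj, k, name in self._walk_buffers()}
        for k, v in state.items():
            if k.startswith("buffer:"):
                obj, name = buffer_owners[k[len("buffer:"):]]
                setattr(obj, name, v.copy())

    def _walk_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v._walk_buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._walk_buffers(f"{key}.{i}.")
        for name in getattr(self, "_buffer_names", ()):
            yield self, f"{prefix}{name}", name


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _uniform(rng, (in_features, out_features), in_features)
        self.bias = _uniform(rng, (out_features,), in_features)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Conv1d(Module):
    """Same-length 1-D convolution (odd kernel), channels last."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for exact same-length padding")
        fan_in = in_channels * kernel_size
        self.weight = _uniform(rng, (kernel_size, in_channels, out_channels), fan_in)
        self.bias = _uniform(rng, (out_channels,), fan_in)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d_same(x, self.weight, self.bias)


class BatchNorm(Module):
    """Batch normalisation over all axes except the last (feature) axis."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            out, mu, var = ag.batch_norm_train(x, self.gamma, self.beta, axes, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.astype(np.float32))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.astype(np.float32))
            return out
        scale = self.gamma * Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        shift = self.beta - scale * Tensor(self.running_mean)
        return x * scale + shift


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        return ag.dropout(x, self.p, self.rng)


class LSTMCellParams(Module):
    """Parameters for one LSTM direction; gate order (i, f, g, o)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.w_ih = _uniform(rng, (input_size, 4 * hidden_size), hidden_size)
        self.w_hh = _uniform(rng, (hidden_size, 4 * hidden_size), hidden_size)
        self.bias = _uniform(rng, (4 * hidden_size,), hidden_size)
        self.hidden_size = hidden_size


class BiLSTM(Module):
    """Single-layer bidirectional LSTM; input (n, T, c) -> (n, T, 2*hidden)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTMCellParams(input_size, hidden_size, rng)
        self.bwd = LSTMCellParams(input_size, hidden_size, rng)
        self.hidden_size = hidden_size

    def __call__(self, x: Tensor) -> Tensor:
        fwd = ag.lstm_direction(x, self.fwd.w_ih, self.fwd.w_hh, self.fwd.bias,
                                reverse=False)
        bwd = ag.lstm_direction(x, self.bwd.w_ih, self.bwd.w_hh, self.bwd.bias,
                                reverse=True)
        return ag.concat([fwd, bwd], axis=2)  # (n, T, 2H)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with learned Q, K, V and output maps.

    Stores the most recent per-head attention matrices (detached, shape
    (n, heads, T, T)) in ``last_attention`` for interpretability traces.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("attention dim must be divisible by the head count")
        self.dim = dim
        self.heads = heads
        self.d_k = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, n: int, T: int) -> Tensor:
        return ag.transpose(ag.reshape(x, (n, T, self.heads, self.d_k)), (0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        n, T, _ = x.shape
        q = self._split(self.q(x), n, T)
        k = self._split(self.k(x), n, T)
        v = self._split(self.v(x), n, T)
        ctx, alpha = ag.scaled_dot_attention(q, k, v)  # (n, heads, T, d_k)
        self.last_attention = alpha
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (n, T, self.dim))
        return self.out(ctx)


class SqueezeExcite(Module):
    """Channel-wise attention: global average -> bottleneck -> sigmoid gates.

    ``identity_gates=True`` bypasses the gating (all gates forced to 1),
    reducing the stage to the plain convolution it wraps.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.identity_gates = False
        self.last_gates: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if self.identity_gates:
            self.last_gates = np.ones((x.shape[0], x.shape[2]), dtype=np.float32)
            return x
        squeeze = ag.tmean(x, axis=1)  # (n, c)
        gates = ag.sigmoid(self.fc2(ag.relu(self.fc1(squeeze))))
        self.last_gates = gates.data.copy()
        return ag.mul(x, ag.reshape(gates, (x.shape[0], 1, x.shape[2])))
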