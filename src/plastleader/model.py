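"""The hybrid convolutional-recurrent leader-sequence classifier.

Architecture (channels-last throughout):

1. conv(k=3) -> batch norm -> ReLU, with a 1x1-projected residual around it;
2. three parallel convolutions (k=3, 5, 7, same-length padding) concatenated,
   gated by channel-wise (squeeze-and-excitation) attention, batch-normed,
   with a second 1x1-projected residual added *before* pooling;
3. max-pool (size 2) and dropout 0.5;
4. bidirectional LSTM (``lstm_hidden`` units per direction);
5. multi-head scaled-dot-product self-attention over the LSTM output,
   mean-pooled along the sequence into a context vector;
6. two fully connected layers (batch norm -> ReLU -> dropout 0.3 each) and a
   linear head; softmax is applied at evaluation, training consumes logits.

Both convolutional stages preserve sequence length before pooling, so the
residual additions are shape-legal, and the attention matrices, final
convolutional feature maps and input gradients are all exposed for the
interpretability module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.layers import (BatchNorm, BiLSTM, Conv1d, Dropout, Linear, Module,
                        MultiHeadSelfAttention, SqueezeExcite)
from .encoding import EncodedBatch


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters; a model is a pure function of these."""

    input_channels: int = 5
    seq_length: int = 300
    conv1_kernel: int = 3
    multi_kernels: tuple[int, int, int] = (3, 5, 7)
    conv_channels: int = 64
    channel_attention_reduction: int = 16
    pool_size: int = 2
    conv_dropout: float = 0.5
    lstm_hidden: int = 256
    attention_heads: int = 4
    fc_sizes: tuple[int, int] = (256, 512)
    fc_dropout: float = 0.3
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if (2 * self.lstm_hidden) % self.attention_heads != 0:
            raise ValueError("2*lstm_hidden must be divisible by attention_heads")
        for k in (self.conv1_kernel, *self.multi_kernels):
            if k % 2 == 0:
                raise ValueError("convolution kernels must be odd for same-length padding")
        if self.seq_length < self.pool_size:
            raise ValueError("seq_length must be at least pool_size")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("multi_kernels", "fc_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ForwardTrace:
    """Intermediate quantities of one evaluation-mode forward pass."""

    logits: np.ndarray          # (n, n_classes)
    probabilities: np.ndarray   # softmax of logits
    conv_features: np.ndarray   # (n, L, C') final conv-stage activations, pre-pool
    attention: np.ndarray       # (n, heads, T, T) row-stochastic matrices
    context: np.ndarray         # (n, 2*lstm_hidden)


class LeaderNet(Module):
    """See the module docstring for the layer graph."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.conv_channels
        cat_channels = c * len(config.multi_kernels)
        self.conv1 = Conv1d(config.input_channels, c, config.conv1_kernel, rng)
        self.bn1 = BatchNorm(c)
        self.res1 = Conv1d(config.input_channels, c, 1, rng)  # 1x1 projection
        self.branches = [Conv1d(c, c, k, rng) for k in config.multi_kernels]
        self.se = SqueezeExcite(cat_channels, config.channel_attention_reduction, rng)
        self.bn2 = BatchNorm(cat_channels)
        self.res2 = Conv1d(c, cat_channels, 1, rng)
        drop_rng = np.random.default_rng(rng.integers(2**31))
        self.conv_drop = Dropout(config.conv_dropout, drop_rng)
        self.lstm = BiLSTM(cat_channels, config.lstm_hidden, rng)
        d = 2 * config.lstm_hidden
        self.attn = MultiHeadSelfAttention(d, config.attention_heads, rng)
        f1, f2 = config.fc_sizes
        self.fc1 = Linear(d, f1, rng)
        self.bnf1 = BatchNorm(f1)
        self.fc2 = Linear(f1, f2, rng)
        self.bnf2 = BatchNorm(f2)
        self.fc_drop1 = Dropout(config.fc_dropout, drop_rng)
        self.fc_drop2 = Dropout(config.fc_dropout, drop_rng)
        self.head = Linear(f2, config.n_classes, rng)
        self._last_conv_features: np.ndarray | None = None
        self._last_context: np.ndarray | None = None

    # -- forward -------------------------------------------------------
    def __call__(self, x: ag.Tensor | np.ndarray) -> ag.Tensor:
        x = ag.as_tensor(x)
        if x.shape[1] != self.config.seq_length:
            raise ValueError(
                f"batch length {x.shape[1]} != configured seq_length "
                f"{self.config.seq_length}"
            )
        # stage 1: conv -> BN -> ReLU, residual
        h1 = ag.relu(self.bn1(self.conv1(x)))
        s1 = h1 + self.res1(x)
        # stage 2: multi-kernel conv -> concat -> channel attention -> BN,
        # residual added before pooling
        cat = ag.concat([b(s1) for b in self.branches], axis=2)
        z = self.bn2(self.se(cat))
        z = z + self.res2(s1)
        self._last_conv_features = z.data.copy()
        p = self.conv_drop(nn.autograd.max_pool1d(z, self.config.pool_size))
        # recurrent stage
        y = self.lstm(p)
        a = self.attn(y)
        ctx = ag.tmean(a, axis=1)  # sequence-mean context vector
        self._last_context = ctx.data.copy()
        f = self.fc_drop1(ag.relu(self.bnf1(self.fc1(ctx))))
        f = self.fc_drop2(ag.relu(self.bnf2(self.fc2(f))))
        return self.head(f)

    def predict_proba(self, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode class probabilities, computed without taping."""
        was_training = self.training
        self.eval()
        try:
            out = []
            with nn.no_grad():
                for i in range(0, len(data), batch_size):
                    logits = self(data[i:i + batch_size])
                    out.append(ag.softmax(logits, axis=1).data)
            return np.concatenate(out, axis=0)
        finally:
            self.train(was_training)

    def predict(self, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(data, batch_size).argmax(axis=1)


def build_model(config: ModelConfig) -> LeaderNet:
    """Construct the classifier; parameter initialisation depends only on
    ``config.seed``."""
    return LeaderNet(config)


def forward_trace(model: LeaderNet, batch: EncodedBatch | np.ndarray) -> ForwardTrace:
    """Evaluation-mode forward pass exposing conv features, attention and context."""
    data = batch.data if isinstance(batch, EncodedBatch) else np.asarray(batch)
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            logits = model(data)
            probs = ag.softmax(logits, axis=1)
    finally:
        model.train(was_training)
    return ForwardTrace(
        logits=logits.data.copy(),
        probabilities=probs.data.copy(),
        conv_features=model._last_conv_features,
        attention=model.attn.last_attention,
        context=model._last_context,
    )


def count_parameters(model: Module) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: LeaderNet, path: str | Path) -> None:
    """Write parameters (binary .npz) with a JSON sidecar of the config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(model.config.to_json())


def load_checkpoint(path: str | Path) -> LeaderNet:
    path = Path(path)
    config = ModelConfig.from_json(path.with_suffix(".json").read_text())
    model = build_model(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
        model.load_state_dict({k: f[k] for k in f.files})
    return model
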