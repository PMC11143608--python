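"""Self-attentive temporal convolutional classifier and comparison baselines.

The main model stacks residual blocks of two weight-normalised causal
dilated convolutions (level i uses dilation base**i), feeds the resulting
feature sequence through a single-head scaled dot-product self-attention
layer with learned Q/K/V projections, adds the attention output back to its
input, average-pools over time and maps to two softmax units.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .nn.autograd import Tensor, avg_pool1d, conv1d, softmax
from .nn.layers import CausalConv1d, Conv1dSame, Dropout, Linear, Module

MODEL_KINDS = ("tcnsa", "tcn", "sa", "cnn")
_ACTIVATIONS = ("relu", "sigmoid", "tanh")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters; defaults are the reference configuration."""

    n_levels: int = 2
    kernel_size: int = 4
    hidden_width: int = 164
    dilation_base: int = 2
    dropout: float = 0.1
    attention_dim: Optional[int] = None  # fixed equal to hidden_width
    n_classes: int = 2
    in_channels: int = 19
    in_length: int = 200
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.n_levels < 1 or self.hidden_width < 1:
            raise ValueError("kernel_size, n_levels, hidden_width must be >= 1")
        if self.dilation_base < 1:
            raise ValueError("dilation_base must be >= 1")
        if self.attention_dim is not None and self.attention_dim != self.hidden_width:
            raise ValueError("attention_dim must equal hidden_width")
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")

    @property
    def d_m(self) -> int:
        return self.hidden_width


def receptive_span(d: int, k: int) -> int:
    """Historical span added by one causal convolution layer: d * (k - 1)."""
    if d < 1 or k < 1:
        raise ValueError("dilation and kernel size must be >= 1")
    return d * (k - 1)


def total_receptive_field(config: ModelConfig) -> int:
    """Samples visible to the last output of the stacked blocks (attention excluded)."""
    span = 0
    for level in range(config.n_levels):
        d = config.dilation_base ** level
        span += 2 * receptive_span(d, config.kernel_size)  # two conv layers per block
    return 1 + span


def causal_dilated_conv(
    x: np.ndarray,
    weights: np.ndarray,
    dilation: int,
    bias: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stateless causal dilated convolution on a (c_in, T) sequence.

    Left zero-padding of d*(k-1) keeps the output length equal to T, and the
    output at time t depends only on inputs at times <= t.
    """
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if x.ndim != 2 or weights.ndim != 3:
        raise ValueError("expected x (c_in, T) and weights (c_out, c_in, k)")
    k = weights.shape[2]
    b = None if bias is None else Tensor(np.asarray(bias, dtype=np.float64))
    out = conv1d(Tensor(x[None]), Tensor(weights), b,
                 dilation=dilation, pad_left=dilation * (k - 1), pad_right=0)
    return out.data[0]


@dataclass
class AttentionInput:
    """Key/value/query matrices sharing sequence length and width d_m."""

    M: np.ndarray
    V: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        self.Q = np.asarray(self.Q, dtype=np.float64)
        if not (self.M.shape == self.V.shape == self.Q.shape) or self.M.ndim != 2:
            raise ValueError("M, V, Q must be 2-D with identical shapes")
        if self.M.shape[1] == 0:
            raise ValueError("d_m must be positive")

    @property
    def d_m(self) -> int:
        return self.M.shape[1]


def attention_weights(a: AttentionInput) -> np.ndarray:
    """Row-wise softmax of Q M^T / sqrt(d_m); every row sums to 1."""
    scores = (a.Q @ a.M.T) / math.sqrt(a.d_m)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def self_attention(a: AttentionInput) -> np.ndarray:
    """Scaled dot-product attention: softmax(Q M^T / sqrt(d_m)) V."""
    return attention_weights(a) @ a.V


class ResidualBlock(Module):
    """o = activation(x + F(x)); F = two causal dilated conv layers with dropout.

    A 1x1 convolution matches channel widths on the shortcut when needed, so
    input and output sequence lengths always agree.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 dropout_p: float, activation: str, rng: np.random.Generator):
        super().__init__()
        self.conv1 = CausalConv1d(c_in, c_out, kernel_size, dilation, rng)
        self.drop1 = Dropout(dropout_p)
        self.conv2 = CausalConv1d(c_out, c_out, kernel_size, dilation, rng)
        self.drop2 = Dropout(dropout_p)
        self.shortcut = (
            None if c_in == c_out
            else CausalConv1d(c_in, c_out, 1, 1, rng, weight_norm=False)
        )
        self.activation = activation

    def _act(self, x: Tensor) -> Tensor:
        if self.activation == "relu":
            return x.relu()
        if self.activation == "sigmoid":
            return x.sigmoid()
        return x.tanh()

    def forward(self, x: Tensor) -> Tensor:
        y = self.drop1(self._act(self.conv1(x)))
        y = self.drop2(self._act(self.conv2(y)))
        s = x if self.shortcut is None else self.shortcut(x)
        return self._act(s + y)


class _AttentionHead(Module):
    """Single-head self-attention with learned Q/K/V projections and residual add."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.proj_q = Linear(width, width, rng)
        self.proj_k = Linear(width, width, rng)
        self.proj_v = Linear(width, width, rng)
        self.width = width

    def forward(self, h: Tensor) -> Tensor:
        # h: (batch, T, width)
        q = self.proj_q(h)
        k = self.proj_k(h)
        v = self.proj_v(h)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.width))
        return h + softmax(scores, axis=-1) @ v


class SequenceClassifier(Module):
    """Shared skeleton: feature extractor -> optional attention -> pool -> head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config

    def logits(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        return self.logits(x)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities in evaluation mode; rows sum to 1."""
        was_training = self.training
        self.eval_mode()
        probs = softmax(self.logits(Tensor(np.asarray(X, dtype=np.float64))), axis=-1).data
        if was_training:
            self.train_mode()
        return probs


class TCNWithAttention(SequenceClassifier):
    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 use_attention: bool = True):
        super().__init__(config)
        c = config.hidden_width
        blocks: List[ResidualBlock] = []
        c_in = config.in_channels
        for level in range(config.n_levels):
            blocks.append(ResidualBlock(
                c_in, c, config.kernel_size, config.dilation_base ** level,
                config.dropout, config.activation, rng,
            ))
            c_in = c
        self.blocks = blocks
        self.attention = _AttentionHead(c, rng) if use_attention else None
        self.head = Linear(c, config.n_classes, rng)

    def feature_sequence(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x  # (batch, width, T)

    def logits(self, x: Tensor) -> Tensor:
        h = self.feature_sequence(x).swapaxes(1, 2)  # (batch, T, width)
        if self.attention is not None:
            h = self.attention(h)
        pooled = h.mean(axis=1)
        return self.head(pooled)


class AttentionOnlyClassifier(SequenceClassifier):
    """Per-timestep linear embedding -> self-attention -> pool -> head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__(config)
        c = config.hidden_width
        self.embed = Linear(config.in_channels, c, rng)
        self.attention = _AttentionHead(c, rng)
        self.head = Linear(c, config.n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        h = self.embed(x.swapaxes(1, 2)).relu()  # (batch, T, width)
        h = self.attention(h)
        return self.head(h.mean(axis=1))


class PlainCNNClassifier(SequenceClassifier):
    """Two non-causal convolution + average-pool stages and a linear head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__(config)
        c = config.hidden_width
        self.conv1 = Conv1dSame(config.in_channels, c, 5, rng)
        self.conv2 = Conv1dSame(c, c, 5, rng)
        self.head = Linear(c, config.n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        h = avg_pool1d(self.conv1(x).relu(), 2)
        h = avg_pool1d(self.conv2(h).relu(), 2)
        return self.head(h.mean(axis=2))


def build_model(config: ModelConfig, seed: int = 0) -> TCNWithAttention:
    """The full attention-augmented temporal convolutional classifier."""
    return TCNWithAttention(config, np.random.default_rng(seed), use_attention=True)


def build_baseline(kind: str, config: ModelConfig, seed: int = 0) -> SequenceClassifier:
    """Comparison models: 'tcn' (no attention), 'sa', 'cnn' — or 'tcnsa' itself."""
    rng = np.random.default_rng(seed)
    if kind == "tcnsa":
        return TCNWithAttention(config, rng, use_attention=True)
    if kind == "tcn":
        return TCNWithAttention(config, rng, use_attention=False)
    if kind == "sa":
        return AttentionOnlyClassifier(config, rng)
    if kind == "cnn":
        return PlainCNNClassifier(config, rng)
    raise ValueError(f"unknown model kind: {kind!r} (expected one of {MODEL_KINDS})")


def count_parameters(model: Module) -> int:
    """Total of trainable weight and bias scalars.

    Weight-normalised layers are counted as their underlying weight tensor
    plus bias; the per-channel gain vector of the reparameterisation is
    excluded by convention.
    """
    return sum(p.data.size for p in model.parameters() if p.counted)


def parameter_count_formula(config: ModelConfig) -> int:
    """Closed-form count for the attention-augmented model (cross-check)."""
    k, c = config.kernel_size, config.hidden_width
    total = 0
    c_in = config.in_channels
    for _ in range(config.n_levels):
        total += c * c_in * k + c          # conv1
        total += c * c * k + c             # conv2
        if c_in != c:
            total += c * c_in + c          # 1x1 shortcut
        c_in = c
    total += 3 * (c * c + c)               # Q/K/V projections
    total += c * config.n_classes + config.n_classes
    return total
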