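"""Parameterised building blocks on top of the autograd engine."""
from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autograd import Tensor, conv1d, dropout


class Parameter(Tensor):
    """A trainable tensor.

    ``counted`` marks whether the tensor contributes to the reported
    parameter total: weight-normalisation gain vectors are trained but, by
    convention, a reparameterised layer is counted as its underlying weight
    tensor plus bias only.
    """

    __slots__ = ("counted",)

    def __init__(self, data: np.ndarray, counted: bool = True):
        super().__init__(data, requires_grad=True)
        self.counted = counted


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> Iterator[Parameter]:
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Parameter):
                    yield value

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train_mode(self) -> None:
        for mod in self.modules():
            mod.training = True

    def eval_mode(self) -> None:
        for mod in self.modules():
            mod.training = False

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for mod in self.modules():
            if isinstance(mod, Dropout):
                mod.rng = rng

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    """Affine map applied to the last axis: x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_uniform_init(rng, (n_in, n_out), n_in))
        self.bias = Parameter(_uniform_init(rng, (n_out,), n_in))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class CausalConv1d(Module):
    """Left-padded dilated convolution; output at t sees inputs at times <= t.

    With ``weight_norm`` the effective kernel is g * v / ||v|| (norm over the
    (c_in, k) axes per output channel), the standard TCN parameterisation.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, weight_norm: bool = True):
        super().__init__()
        if kernel_size < 1 or dilation < 1:
            raise ValueError("kernel_size and dilation must be >= 1")
        self.kernel_size = kernel_size
        self.dilation = dilation
        w0 = _uniform_init(rng, (c_out, c_in, kernel_size), c_in * kernel_size)
        self.weight_norm = weight_norm
        if weight_norm:
            self.weight_v = Parameter(w0)
            self.gain = Parameter(
                np.sqrt((w0 ** 2).sum(axis=(1, 2))), counted=False
            )
        else:
            self.weight = Parameter(w0)
        self.bias = Parameter(_uniform_init(rng, (c_out,), c_in * kernel_size))

    def effective_weight(self) -> Tensor:
        if not self.weight_norm:
            return self.weight
        norm = self.weight_v.pow(2.0).sum(axis=(1, 2), keepdims=True).sqrt()
        c_out = self.weight_v.shape[0]
        return self.weight_v * (self.gain.reshape(c_out, 1, 1) / norm)

    def forward(self, x: Tensor) -> Tensor:
        pad = self.dilation * (self.kernel_size - 1)
        return conv1d(x, self.effective_weight(), self.bias,
                      dilation=self.dilation, pad_left=pad, pad_right=0)


class Conv1dSame(Module):
    """Plain (non-causal) convolution with symmetric 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        self.weight = Parameter(
            _uniform_init(rng, (c_out, c_in, kernel_size), c_in * kernel_size)
        )
        self.bias = Parameter(_uniform_init(rng, (c_out,), c_in * kernel_size))

    def forward(self, x: Tensor) -> Tensor:
        left = (self.kernel_size - 1) // 2
        right = self.kernel_size - 1 - left
        return conv1d(x, self.weight, self.bias, dilation=1,
                      pad_left=left, pad_right=right)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: Optional[np.random.Generator] = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        return dropout(x, self.p, self.rng)
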