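"""Layer modules built on the autodiff tensor.

He (Kaiming) initialization is used for every convolution and dense
layer; batch-norm scales start at one and shifts at zero.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class with parameter registration and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray],
                        strict: bool = True) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        own = set(own_params) | set(own_bufs)
        missing = own - set(state)
        unexpected = set(state) - own
        if strict and (missing or unexpected):
            raise KeyError(
                f"state mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(unexpected)}"
            )
        for name, arr in state.items():
            target = own_params.get(name)
            if target is not None:
                if target.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                target.data = np.asarray(arr, dtype=target.data.dtype).copy()
                continue
            buf = own_bufs.get(name)
            if buf is not None:
                if buf.shape != arr.shape:
                    raise ValueError(f"shape mismatch for buffer {name}")
                buf[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...],
              fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """Same-padded 1-D convolution, (N, C_in, L) -> (N, C_out, ceil(L/stride))."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.weight = Tensor(
            he_normal(rng, (out_channels, in_channels, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return T.conv1d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 *, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            he_normal(rng, (in_features, out_features), in_features),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_features), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean",
                             np.zeros(channels, dtype=T.default_dtype()))
        self.register_buffer("running_var",
                             np.ones(channels, dtype=T.default_dtype()))

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return T.dropout(x, self.p, self.rng, self.training)


class SqueezeExcite(Module):
    """Channel gating from pooled global statistics.

    GAP over length -> FC to a bottleneck of ``max(C // ratio, 1)`` with
    ReLU -> FC back to C with a sigmoid -> per-channel rescaling.  With
    all excitation weights and biases zero the gate is exactly
    sigmoid(0) = 0.5 for every channel.
    """

    def __init__(self, channels: int, ratio: int, *, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = T.global_avg_pool(x)                       # (N, C)
        s = T.relu(self.fc1(s))
        g = T.sigmoid(self.fc2(s))                     # (N, C)
        gate = T.reshape(g, (g.shape[0], g.shape[1], 1))
        return T.mul(x, gate)
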