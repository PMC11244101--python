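"""Layer primitives built on the autograd core: Conv2d, BatchNorm2d, Linear.

Weight initialization is the seeded uniform fan-in scheme U(-1/sqrt(fan_in),
1/sqrt(fan_in)); every layer draws from the Generator handed to it at
construction, so a model built from one seed is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "ModuleList"]


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
        return params

    def _apply_mode(self, training: bool) -> None:
        self.training = training
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v._apply_mode(training)

    def train(self) -> "Module":
        self._apply_mode(True)
        return self

    def eval(self) -> "Module":
        self._apply_mode(False)
        return self

    # named state (parameters + buffers) for checkpointing
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                state[prefix + k] = v.data
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, np.ndarray):   # buffers (running stats)
                state[prefix + k] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[prefix + k], dtype=np.float32)
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(state[prefix + k])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules: list[Module]):
        for i, mod in enumerate(modules):
            setattr(self, f"m{i}", mod)
        self._n = len(modules)

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __len__(self) -> int:
        return self._n


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, shape).astype(np.float32),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int | tuple,
                 rng: np.random.Generator, stride: tuple[int, int] = (1, 1),
                 padding: str | tuple[int, int] = "same", bias: bool = True):
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if padding == "same":
            padding = ((kh - 1) // 2, (kw - 1) // 2)
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kh * kw
        self.weight = _uniform(rng, (out_channels, in_channels, kh, kw), fan_in)
        self.bias = _uniform(rng, (out_channels,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch statistics while training; running averages at inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            sd_inv = Tensor((self.running_var.reshape(shape) + self.eps) ** -0.5)
            xhat = (x - mu) * sd_inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = _uniform(rng, (in_features, out_features), in_features)
        self.bias = _uniform(rng, (out_features,), in_features) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out if self.bias is None else out + self.bias
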