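"""Layer building blocks on top of the autodiff tensor.

Conventions: NHWC layout, He-uniform initialisation for convolutions,
Glorot-uniform for dense layers, batch-norm over all axes but the
channel axis with running statistics for inference mode.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "DepthwiseConv3x3",
    "PointwiseConv",
    "Dense",
    "BatchNorm",
    "ReLU",
    "Sigmoid",
    "HSwish",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Sequential",
    "ACTIVATIONS",
]


class Module:
    """Base class with parameter/submodule discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- flat state dict of parameter and buffer arrays, for checkpoints
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {("param:" + k): v.data for k, v in self.named_parameters()}
        state.update({("buffer:" + k): v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for key, arr in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in checkpoint")
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = arr.astype(np.float64).copy()
            elif kind == "buffer":
                buffers[name] = arr
        # buffers are attributes on (possibly nested) modules
        for name, arr in buffers.items():
            obj: Module | object = self
            *path, attr = name.split(".")
            for part in path:
                if part.isdigit():
                    obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
                else:
                    obj = getattr(obj, part)
            setattr(obj, attr, arr.astype(np.float64).copy())


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x


def he_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 spatial filter ("same" padding)."""

    def __init__(self, channels: int, stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = Parameter(he_uniform((3, 3, channels), fan_in=9, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        return x.depthwise_conv3x3(self.weight, stride=self.stride)


class PointwiseConv(Module):
    """1x1 channel-mixing convolution, bias-free (batch norm follows it)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(
            he_uniform((in_channels, out_channels), fan_in=in_channels, rng=rng)
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul_last(self.weight)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(
            glorot_uniform((in_features, out_features), in_features, out_features, rng)
        )
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul_last(self.weight) + self.bias


class BatchNorm(Module):
    """Batch normalisation over every axis except the trailing channel axis.

    Inference mode uses exponential running averages of the batch
    moments (momentum 0.9).
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 fuse_relu: bool = False):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.fuse_relu = fuse_relu
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import batch_norm

        if self.training:
            out, mu, var = batch_norm(x, self.gamma, self.beta, self.eps,
                                      relu=self.fuse_relu)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * np.asarray(mu, np.float64)
            self.running_var = m * self.running_var + (1 - m) * np.asarray(var, np.float64)
            return out
        out, _, _ = batch_norm(x, self.gamma, self.beta, self.eps,
                               mean=self.running_mean, var=self.running_var,
                               relu=self.fuse_relu)
        return out

    def freeze_identity(self) -> None:
        """Pin to the identity transform (unit gamma/variance, zero mean/beta).

        Used by tests that need the surrounding arithmetic to be exactly
        reproducible by hand.
        """
        self.gamma.data = np.ones_like(self.gamma.data)
        self.beta.data = np.zeros_like(self.beta.data)
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var) - self.eps
        self.training = False


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class HSwish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hswish()


ACTIVATIONS = {"relu": ReLU, "sigmoid": Sigmoid, "hswish": HSwish}


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2x2()


class GlobalAvgPool(Module):
    """(B, H, W, C) -> (B, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(1, 2))
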