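"""Layer modules built on the tensor engine: Conv2d, ConvTranspose2d,
InstanceNorm2d and a Module base class with a flat, ordered state dict."""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, instance_norm2d

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "InstanceNorm2d"]


class Module:
    """Minimal container with recursive parameter discovery.

    Parameters are `Tensor`s with ``requires_grad=True``; submodules are any
    attribute that is itself a `Module` or a list of them.
    """

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Tensor]":
        out: OrderedDict[str, Tensor] = OrderedDict()
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.data.copy()) for k, v in self.named_parameters().items())

    def load_state_dict(self, state: dict) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int, rng: np.random.Generator):
        k = kernel_size
        self.padding = padding
        self.weight = Tensor(
            _he_normal(rng, (out_channels, in_channels, k, k), in_channels * k * k),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """2x2 stride-2 learnable upsampling."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.weight = Tensor(
            _he_normal(rng, (in_channels, out_channels, 2, 2), in_channels * 4),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, affine: bool = True, eps: float = 1e-5):
        self.eps = eps
        if affine:
            self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
            self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        else:
            self.weight = None
            self.bias = None

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm2d(x, self.weight, self.bias, eps=self.eps)
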