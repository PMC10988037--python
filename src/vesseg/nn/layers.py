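"""Layer modules and the Adam optimiser for the segmentation stack.

Modules hold named parameter Tensors and compose; initialisation is
He-style (fan-in scaled) from an explicit seeded generator so two builds
with the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from . import functional as F

__all__ = ["Module", "Conv3d", "ConvTranspose3d2x", "PReLU", "Dropout", "Adam"]


class Module:
    """Base class: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1, dilation: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.padding = padding
        fan_in = in_channels * kernel_size**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels) + (kernel_size,) * 3),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, stride=self.stride,
                        dilation=self.dilation, padding=self.padding)


class ConvTranspose3d2x(Module):
    """2x2x2 stride-2 transposed convolution (exact 2x spatial upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        std = np.sqrt(2.0 / (in_channels * 8))
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, 2, 2, 2)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d_2x(x, self.weight, self.bias)


class PReLU(Module):
    """Per-channel learnable negative slope, initialised at 0.25."""

    def __init__(self, n_channels: int, init: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.full(n_channels, init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.slope)


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout p must lie in [0, 1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list, lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
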