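"""Neural-network layers and the Adam optimizer on top of :mod:`autodiff`.

Modules follow the familiar container pattern: attributes that are
``Module`` instances (or lists of them) are registered children, and
``parameters()`` / ``state_dict()`` walk the tree.  Weight init is
Kaiming-uniform driven by an explicit ``numpy.random.Generator`` so that a
single root seed makes model construction fully reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, batchnorm2d, conv2d, maxpool2x2

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ConvBNReLU",
    "MaxPool2d",
    "Adam",
]


class Module:
    """Base class: child registration, parameter iteration, train/eval."""

    def __init__(self):
        self.training = True

    # -- tree walking ----------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    # -- modes -----------------------------------------------------------
    def train(self):
        self.training = True
        for _, child in self.children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self.children():
            child.eval()
        return self

    # -- state -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buf:"):
                buf = buffers[key[4:]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {p.data.shape} vs {value.shape}"
                    )
                p.data = value.astype(np.float32).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def append(self, module: Module):
        self.items.append(module)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                     fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """2-D convolution, zero padding, optional bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        self.stride, self.padding, self.dilation = stride, padding, dilation
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_channels, in_channels, k, k), fan_in),
            requires_grad=True,
        )
        if bias:
            bound = 1.0 / math.sqrt(fan_in)
            self.bias = Tensor(
                rng.uniform(-bound, bound, size=out_channels).astype(np.float32),
                requires_grad=True,
            )
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self.training,
                           momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    """Conv (no bias) → BatchNorm → ReLU — the building block used
    throughout the encoder, bridge and decoder."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 dilation: int = 1, relu: bool = True):
        super().__init__()
        padding = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng,
                           stride=stride, padding=padding, dilation=dilation,
                           bias=False)
        self.bn = BatchNorm2d(out_channels)
        self.relu = relu

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv(x))
        return x.relu() if self.relu else x


class MaxPool2d(Module):
    """2×2, stride 2."""

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class Adam:
    """Adam with the standard bias correction (Kingma & Ba defaults)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
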