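"""Multi-scale bridge (DenseASPP) and spatial–channel attention (SCA).

DenseASPP stacks dilated 3×3 branches (dilations 3/6/12/18 in the
canonical preset) with dense connectivity: branch ``i`` consumes the
concatenation of the block input and every earlier branch's output, so
the effective receptive-field pyramid is much denser than plain ASPP at
the same parameter cost.  Each branch is a 1×1 bottleneck followed by the
dilated 3×3; a final 1×1 projection compresses the full concatenation.

The SCA module applies two attention paths to the same input and fuses
them:

* spatial attention — per-pixel max and mean over channels, a 1×1 conv
  on the two pooled maps, sigmoid → weight map ``M_s ∈ (0,1)^{1×H×W}``
  multiplied into the input;
* channel attention — global max and average pooling, a shared
  three-layer bottleneck ``C → C/8 → C/8 → C`` applied to both pooled
  vectors, a 1×1 transform of their concatenation, sigmoid → weight
  vector ``M_c ∈ (0,1)^{C×1×1}`` multiplied into the input;
* fusion — the two attended tensors are concatenated (2C) and projected
  back to C by a 1×1 conv–BN–ReLU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, ConvBNReLU, Module, ModuleList

__all__ = [
    "DenseASPPSpec",
    "AttentionMaps",
    "DenseASPP",
    "SpatialAttention",
    "ChannelAttention",
    "SCA",
]


@dataclass(frozen=True)
class DenseASPPSpec:
    """Dilations and widths of the bridge."""

    dilation_rates: tuple[int, ...] = (3, 6, 12, 18)
    branch_channels: int = 256
    bottleneck_channels: int = 128
    out_channels: int = 512

    def __post_init__(self):
        if not self.dilation_rates:
            raise ValueError("dilation_rates must be non-empty")
        if any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilations must be >= 1")
        if list(self.dilation_rates) != sorted(set(self.dilation_rates)):
            raise ValueError("dilations must be strictly increasing")


@dataclass
class AttentionMaps:
    """Sigmoid-bounded weights: per-pixel map and per-channel vector."""

    spatial_weights: Tensor | None = None  # N×1×H×W, entries in (0,1)
    channel_weights: Tensor | None = None  # N×C×1×1, entries in (0,1)


class DenseASPP(Module):
    """Densely connected atrous spatial pyramid over a C×H×W map."""

    def __init__(self, in_channels: int, spec: DenseASPPSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.branches = ModuleList()
        cin = in_channels
        for d in spec.dilation_rates:
            # 1×1 bottleneck then the dilated 3×3
            self.branches.append(
                Sequential2(
                    ConvBNReLU(cin, spec.bottleneck_channels, 1, rng),
                    ConvBNReLU(spec.bottleneck_channels, spec.branch_channels,
                               3, rng, dilation=d),
                )
            )
            cin += spec.branch_channels
        self.project = ConvBNReLU(cin, spec.out_channels, 1, rng)
        self.out_channels = spec.out_channels

    def branch_input_channels(self, in_channels: int) -> list[int]:
        """Input width of each branch: C + (i−1)·branch_channels."""
        return [in_channels + i * self.spec.branch_channels
                for i in range(len(self.spec.dilation_rates))]

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for branch in self.branches:
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(branch(inp))
        return self.project(concat(feats, axis=1))


class Sequential2(Module):
    """Two-step pipeline (kept tiny; avoids a generic container here)."""

    def __init__(self, first: Module, second: Module):
        super().__init__()
        self.first = first
        self.second = second

    def forward(self, x: Tensor) -> Tensor:
        return self.second(self.first(x))


class SpatialAttention(Module):
    """Per-pixel attention: sigmoid(1×1 conv over [max_c, mean_c])."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, 1, rng, bias=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x_max = x.max(axis=1, keepdims=True)       # N×1×H×W
        x_avg = x.mean(axis=1, keepdims=True)
        weights = self.conv(concat([x_max, x_avg], axis=1)).sigmoid()
        return weights, weights * x


class ChannelAttention(Module):
    """Per-channel attention with a shared three-layer bottleneck.

    Reduction is C/8 (ceil for small C).  Both globally pooled vectors
    pass through the same fc1→fc2→fc3 stack; their concatenation is
    mapped 2C→C and squashed by a sigmoid.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 8):
        super().__init__()
        r = max(1, math.ceil(channels / reduction))
        self.fc1 = Conv2d(channels, r, 1, rng, bias=True)
        self.fc2 = Conv2d(r, r, 1, rng, bias=True)
        self.fc3 = Conv2d(r, channels, 1, rng, bias=True)
        self.fuse = Conv2d(2 * channels, channels, 1, rng, bias=True)

    def _bottleneck(self, v: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(v)))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        v_max = flat.max(axis=2).reshape(n, c, 1, 1)
        v_avg = flat.mean(axis=2).reshape(n, c, 1, 1)
        x1 = self._bottleneck(v_max)
        x2 = self._bottleneck(v_avg)
        weights = self.fuse(concat([x1, x2], axis=1)).sigmoid()  # N×C×1×1
        return weights, weights * x


class SCA(Module):
    """Spatial–channel attention: both paths on the same input, fused
    2C→C by a 1×1 conv–BN–ReLU."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 8):
        super().__init__()
        self.spatial = SpatialAttention(rng)
        self.channel = ChannelAttention(channels, rng, reduction=reduction)
        self.fusion = ConvBNReLU(2 * channels, channels, 1, rng)
        self.last_maps = AttentionMaps()

    def forward(self, x: Tensor) -> Tensor:
        ws, out_s = self.spatial(x)
        wc, out_c = self.channel(x)
        self.last_maps = AttentionMaps(spatial_weights=ws, channel_weights=wc)
        return self.fusion(concat([out_s, out_c], axis=1))
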