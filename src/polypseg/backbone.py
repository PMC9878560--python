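"""HarDNet68 encoder built from harmonic dense blocks (HDBs).

A harmonic dense block sparsifies DenseNet's all-to-all connectivity:
layer ``l`` receives skip inputs only from layers ``l - 2**n`` for every
``n >= 0`` with ``2**n`` dividing ``l`` (index 0 is the block input).  Key
layers — those with a high 2-adic valuation — are widened by the channel
multiplier ``m`` to balance input/output traffic: a layer whose index is
divisible by ``2**n`` (and no higher power) has ``round_even(k * m**n)``
channels, where ``k`` is the growth rate.  The block output concatenates
the final layer with all odd-indexed layers and is compressed by a 1×1
transition to ``t`` channels.

The canonical HarDNet68 stage plan (growth k, transition t per stage):

====== ======== ===== ======
stride n_layers  k      t
====== ======== ===== ======
4        8       14    128
8       16       16    256
8       16       20    320
16      16       40    640
32       4      160   1024
====== ======== ===== ======

with global multiplier m = 1.7 and a two-conv stem (32, 64).  The encoder
taps a feature pyramid at strides 4/8/16/32 with 128/320/640/1024 channels
(the second stride-8 block feeds the pyramid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .nn import ConvBNReLU, MaxPool2d, Module, ModuleList

__all__ = [
    "HDBSpec",
    "EncoderSpec",
    "FeaturePyramid",
    "link_targets",
    "layer_width",
    "HarDBlock",
    "HarDNetEncoder",
    "CANONICAL_ENCODER",
    "TINY_ENCODER",
]


# --------------------------------------------------------------- specs

@dataclass(frozen=True)
class HDBSpec:
    """One harmonic dense block stage."""

    n_layers: int
    growth_rate: int
    multiplier: float
    transition_channels: int
    downsample: bool  # halve spatial resolution on entry to this stage

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if self.multiplier < 1.0:
            raise ValueError("multiplier must be >= 1.0")
        if self.transition_channels < self.growth_rate:
            raise ValueError("transition_channels must be >= growth_rate")


@dataclass(frozen=True)
class EncoderSpec:
    """Stem widths plus an ordered list of HDB stages."""

    stem_channels: tuple[int, int] = (32, 64)
    stages: tuple[HDBSpec, ...] = ()
    # strides (relative to the input) at which the pyramid is tapped,
    # given as stage indices into ``stages``
    tap_stages: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.stem_channels) != 2:
            raise ValueError("stem_channels must be a pair")
        if any(i >= len(self.stages) for i in self.tap_stages):
            raise ValueError("tap stage index out of range")


def _hdb(n, k, t, downsample, m=1.7):
    return HDBSpec(n_layers=n, growth_rate=k, multiplier=m,
                   transition_channels=t, downsample=downsample)


#: HarDNet68 preset.  The stem ends at stride 4; stages with
#: ``downsample=True`` pool on entry, giving strides 4/8/8/16/32.
CANONICAL_ENCODER = EncoderSpec(
    stem_channels=(32, 64),
    stages=(
        _hdb(8, 14, 128, downsample=False),
        _hdb(16, 16, 256, downsample=True),
        _hdb(16, 20, 320, downsample=False),
        _hdb(16, 40, 640, downsample=True),
        _hdb(4, 160, 1024, downsample=True),
    ),
    tap_stages=(0, 2, 3, 4),
)

#: A small preset of the same family for CPU smoke fits and tests.
TINY_ENCODER = EncoderSpec(
    stem_channels=(8, 16),
    stages=(
        _hdb(2, 8, 32, downsample=False, m=1.3),
        _hdb(2, 8, 40, downsample=True, m=1.3),
        _hdb(2, 8, 48, downsample=False, m=1.3),
        _hdb(2, 10, 64, downsample=True, m=1.3),
        _hdb(2, 12, 96, downsample=True, m=1.3),
    ),
    tap_stages=(0, 2, 3, 4),
)


@dataclass
class FeaturePyramid:
    """Multi-scale encoder outputs keyed by stride relative to the input."""

    maps: dict[int, Tensor] = field(default_factory=dict)

    def __getitem__(self, stride: int) -> Tensor:
        return self.maps[stride]

    @property
    def strides(self) -> list[int]:
        return sorted(self.maps)


# ------------------------------------------------- harmonic connectivity

def link_targets(layer_index: int) -> set[int]:
    """Indices feeding layer ``layer_index`` under the harmonic rule.

    Layer ``l`` connects to ``l - 2**n`` for every ``n >= 0`` such that
    ``2**n`` divides ``l`` and ``l - 2**n >= 0``.  Index 0 is the block
    input, so the result is never empty.
    """
    if layer_index < 1:
        raise ValueError("layer_index must be >= 1")
    targets = set()
    step = 1
    while layer_index % step == 0:
        if layer_index - step >= 0:
            targets.add(layer_index - step)
        step *= 2
    return targets


def layer_width(layer_index: int, growth_rate: int, multiplier: float) -> int:
    """Channel width of layer ``layer_index``: ``k * m**v2(l)`` rounded to
    the nearest even integer (minimum 2), where ``v2`` is the 2-adic
    valuation of the index."""
    if layer_index < 1:
        raise ValueError("layer_index must be >= 1")
    if growth_rate < 1 or multiplier < 1.0:
        raise ValueError("growth_rate >= 1 and multiplier >= 1.0 required")
    width = float(growth_rate)
    l = layer_index
    while l % 2 == 0:
        width *= multiplier
        l //= 2
    return max(2, int(int(width + 1) / 2) * 2)


class HarDBlock(Module):
    """One harmonic dense block plus its 1×1 transition.

    Each conv layer is Conv3×3–BN–ReLU over the concatenation of its
    harmonic link targets' outputs; the block output concatenates the
    final and all odd-indexed layers, then a 1×1 transition maps it to
    ``spec.transition_channels``.
    """

    def __init__(self, spec: HDBSpec, in_channels: int, rng: np.random.Generator):
        super().__init__()
        if in_channels <= 0:
            raise ValueError("in_channels must be positive")
        self.spec = spec
        widths = {0: in_channels}
        self.links: list[list[int]] = []
        self.layers = ModuleList()
        for l in range(1, spec.n_layers + 1):
            widths[l] = layer_width(l, spec.growth_rate, spec.multiplier)
            links = sorted(link_targets(l))
            self.links.append(links)
            cin = sum(widths[j] for j in links)
            self.layers.append(ConvBNReLU(cin, widths[l], 3, rng))
        self.keep = [l for l in range(1, spec.n_layers + 1)
                     if l % 2 == 1 or l == spec.n_layers]
        cat_channels = sum(widths[l] for l in self.keep)
        self.transition = ConvBNReLU(cat_channels, spec.transition_channels, 1, rng)
        self.out_channels = spec.transition_channels

    def layer_outputs(self, x: Tensor) -> list[Tensor]:
        """Outputs of every layer, index 0 being the block input."""
        outs = [x]
        for links, layer in zip(self.links, self.layers):
            inp = outs[links[0]] if len(links) == 1 else concat(
                [outs[j] for j in links], axis=1
            )
            outs.append(layer(inp))
        return outs

    def forward(self, x: Tensor) -> Tensor:
        outs = self.layer_outputs(x)
        kept = concat([outs[l] for l in self.keep], axis=1)
        return self.transition(kept)


class HarDNetEncoder(Module):
    """Stem (two 3×3 convs, strides 2 then 1, then 2×2 max-pool) followed
    by the HDB stages; emits a :class:`FeaturePyramid` at the tap stages."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c0, c1 = spec.stem_channels
        self.stem0 = ConvBNReLU(3, c0, 3, rng, stride=2)
        self.stem1 = ConvBNReLU(c0, c1, 3, rng)
        self.pool = MaxPool2d()
        self.blocks = ModuleList()
        cin = c1
        stride = 4  # after stem conv (2) and stem pool (2)
        self.stage_strides: list[int] = []
        for st in spec.stages:
            if st.downsample:
                stride *= 2
            self.stage_strides.append(stride)
            block = HarDBlock(st, cin, rng)
            self.blocks.append(block)
            cin = block.out_channels
        self.tap_strides = tuple(self.stage_strides[i] for i in spec.tap_stages)

    @property
    def pyramid_channels(self) -> dict[int, int]:
        return {
            self.stage_strides[i]: self.spec.stages[i].transition_channels
            for i in self.spec.tap_stages
        }

    def forward(self, image: Tensor) -> FeaturePyramid:
        if image.ndim != 4 or image.shape[1] != 3:
            raise ValueError("encoder expects an N×3×H×W tensor")
        h, w = image.shape[2], image.shape[3]
        if h % 32 or w % 32:
            raise ValueError("input height and width must be divisible by 32")
        x = self.pool(self.stem1(self.stem0(image)))
        pyramid = FeaturePyramid()
        taps = set(self.spec.tap_stages)
        for i, block in enumerate(self.blocks):
            if self.spec.stages[i].downsample:
                x = self.pool(x)
            x = block(x)
            if i in taps:
                pyramid.maps[self.stage_strides[i]] = x
        return pyramid
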