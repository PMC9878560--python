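"""The assembled segmentation network.

Encoder (HarDNet68 feature pyramid) → DenseASPP bridge on the deepest
map → three decoder stages, each of which

1. bilinearly upsamples the incoming features ×2,
2. matches the encoder skip's channels with a 1×1 conv–BN–ReLU,
3. multiplies skip and upsampled features elementwise,
4. refines with an SCA attention module,
5. compresses with a 3×3 conv–BN–ReLU to half the width,

followed by a 1×1 conv + sigmoid head upsampled ×4 to the input size.
Decoder widths halve along the way (canonically 512→256→128→64); skips
are consumed deepest-first (strides 16, 8, 4).  The canonical
configuration totals ≈23.1M trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, bilinear_resize
from .backbone import CANONICAL_ENCODER, TINY_ENCODER, EncoderSpec, HarDNetEncoder
from .blocks import SCA, DenseASPP, DenseASPPSpec
from .nn import Conv2d, ConvBNReLU, Module, ModuleList

__all__ = [
    "NetworkSpec",
    "ProbabilityMap",
    "DecoderStage",
    "PolypSegNet",
    "build_network",
    "predict_mask",
    "CANONICAL_NETWORK",
    "TINY_NETWORK",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Everything needed to build the model deterministically."""

    input_size: int = 256
    encoder: EncoderSpec = CANONICAL_ENCODER
    aspp: DenseASPPSpec = DenseASPPSpec()
    decoder_channels: tuple[int, ...] = (256, 128, 64)
    attention_reduction: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if len(self.decoder_channels) != len(self.encoder.tap_stages) - 1:
            raise ValueError(
                "need one decoder stage per skip connection "
                f"({len(self.encoder.tap_stages) - 1} skips, "
                f"{len(self.decoder_channels)} stages)"
            )


CANONICAL_NETWORK = NetworkSpec()

TINY_NETWORK = NetworkSpec(
    input_size=96,
    encoder=TINY_ENCODER,
    aspp=DenseASPPSpec(branch_channels=24, bottleneck_channels=16,
                       out_channels=64),
    decoder_channels=(48, 32, 16),
)


@dataclass
class ProbabilityMap:
    """Sigmoid output of the network: N×1×H×W, entries in (0,1)."""

    values: Tensor

    @property
    def shape(self):
        return self.values.shape

    def numpy(self) -> np.ndarray:
        return self.values.data


class DecoderStage(Module):
    """Upsample ×2 → skip-match 1×1 → elementwise product → SCA → 3×3."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 rng: np.random.Generator, reduction: int = 8):
        super().__init__()
        self.skip_match = ConvBNReLU(skip_channels, in_channels, 1, rng)
        self.sca = SCA(in_channels, rng, reduction=reduction)
        self.refine = ConvBNReLU(in_channels, out_channels, 3, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = bilinear_resize(x, skip.shape[2], skip.shape[3])
        x = x * self.skip_match(skip)
        return self.refine(self.sca(x))


class PolypSegNet(Module):
    """Encoder + DenseASPP + SCA decoder, sigmoid probability output."""

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoder = HarDNetEncoder(spec.encoder, rng)
        channels = self.encoder.pyramid_channels
        strides = sorted(channels)          # e.g. [4, 8, 16, 32]
        self.skip_strides = strides[-2::-1]  # deepest-first skips: 16, 8, 4
        self.aspp = DenseASPP(channels[strides[-1]], spec.aspp, rng)
        self.stages = ModuleList()
        cin = self.aspp.out_channels
        for stride, cout in zip(self.skip_strides, spec.decoder_channels):
            self.stages.append(
                DecoderStage(cin, channels[stride], cout, rng,
                             reduction=spec.attention_reduction)
            )
            cin = cout
        self.head = Conv2d(cin, 1, 1, rng, bias=True)

    def forward(self, image: Tensor | np.ndarray) -> ProbabilityMap:
        if not isinstance(image, Tensor):
            image = Tensor(image)
        if image.ndim == 3:
            image = image.reshape(1, *image.shape)
        n, c, h, w = image.shape
        if c != 3:
            raise ValueError("expected 3-channel input")
        pyramid = self.encoder(image)
        x = self.aspp(pyramid[max(pyramid.strides)])
        for stage, stride in zip(self.stages, self.skip_strides):
            x = stage(x, pyramid[stride])
        logits = self.head(x)
        prob = logits.sigmoid()
        prob = bilinear_resize(prob, h, w)
        return ProbabilityMap(values=prob)


def build_network(spec: NetworkSpec | None = None) -> PolypSegNet:
    """Build the model (canonical preset by default)."""
    return PolypSegNet(spec or CANONICAL_NETWORK)


def predict_mask(prob: ProbabilityMap | np.ndarray, threshold: float = 0.5
                 ) -> np.ndarray:
    """Binarize a probability map: 1 where prob >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    values = prob.numpy() if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    return (values >= threshold).astype(np.uint8)
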