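"""Dataset I/O, preprocessing/augmentation, splitting, and a synthetic
colonoscopy-image generator.

The real-world layout this package targets is the common benchmark
directory pair (``images/`` and ``masks/`` with matching stems, PNG/JPEG
images and PNG masks, foreground = polyp).  The training protocol works
at the source-image level: images are augmented into a fixed number of
variants (rotation always, centre crop and Gaussian blur each with
probability 0.5), split 80/10/10 *before* augmentation so no variant of
one source image can leak across splits, and finally resized to the
network's input size (canonically 256×256).

The synthetic generator emulates the structure of the public polyp sets:
a low-frequency pink/red mucosa-like background, 1–3 low-contrast
elliptical lesions with Gaussian-feathered borders covering 5–40% of the
frame, and specular highlight speckles.  The mask is the union of the
lesion ellipses before feathering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SampleRecord",
    "AugmentSpec",
    "SplitSpec",
    "load_pair",
    "save_pair",
    "load_dataset",
    "save_dataset",
    "resize_pair",
    "augment",
    "split_dataset",
    "synth_generate",
]

MASK_THRESHOLD = 127  # 8-bit mask values strictly above this are polyp


@dataclass
class SampleRecord:
    """One image/mask pair with provenance."""

    image: np.ndarray  # H×W×3 float32 in [0, 1]
    mask: np.ndarray   # H×W uint8 in {0, 1}
    source_id: str = ""
    split: str | None = None  # train / val / test / external_test

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly binary")


@dataclass(frozen=True)
class AugmentSpec:
    """The augmentation protocol: rotation up to ±30°, optional centre
    crop (160×160) + resize back, optional 3×3 Gaussian blur, 20
    variants per source image."""

    crop_size: tuple[int, int] = (160, 160)
    rotation_max_deg: float = 30.0
    blur_sigma: float = 0.8  # 3×3 kernel under the 0.3·((k−1)/2−1)+0.8 rule
    variants_per_image: int = 20
    crop_prob: float = 0.5
    blur_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.variants_per_image < 1:
            raise ValueError("variants_per_image must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ValueError("split fractions must sum to 1")


# ------------------------------------------------------------------ I/O

def load_pair(image_path, mask_path) -> SampleRecord:
    """Read an image/mask pair; image → float [0,1], mask binarized."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    image = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float32) / 255.0
    mask_raw = np.asarray(Image.open(mask_path).convert("L"))
    if image.shape[:2] != mask_raw.shape:
        raise ValueError(
            f"{image_path.name}: image {image.shape[:2]} vs mask {mask_raw.shape}"
        )
    mask = (mask_raw > MASK_THRESHOLD).astype(np.uint8)
    return SampleRecord(image=image, mask=mask, source_id=image_path.stem)


def save_pair(record: SampleRecord, image_path, mask_path) -> None:
    Image.fromarray(
        (np.clip(record.image, 0, 1) * 255).round().astype(np.uint8)
    ).save(image_path)
    Image.fromarray(record.mask * np.uint8(255)).save(mask_path)


def load_dataset(root) -> list[SampleRecord]:
    """Read a directory pair ``root/images`` + ``root/masks``."""
    root = Path(root)
    images_dir, masks_dir = root / "images", root / "masks"
    records = []
    for image_path in sorted(images_dir.iterdir()):
        mask_path = masks_dir / (image_path.stem + ".png")
        if not mask_path.exists():
            raise FileNotFoundError(f"no mask for {image_path.name}")
        records.append(load_pair(image_path, mask_path))
    if not records:
        raise FileNotFoundError(f"no images under {images_dir}")
    return records


def save_dataset(records, root) -> None:
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for record in records:
        stem = record.source_id.replace("/", "_")
        save_pair(record, root / "images" / f"{stem}.png",
                  root / "masks" / f"{stem}.png")


# ------------------------------------------------------- preprocessing

def _resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    pil = Image.fromarray((np.clip(image, 0, 1) * 255).round().astype(np.uint8))
    out = pil.resize((size[1], size[0]), Image.BILINEAR)
    return np.asarray(out, dtype=np.float32) / 255.0


def _resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    pil = Image.fromarray(mask * np.uint8(255))
    out = np.asarray(pil.resize((size[1], size[0]), Image.NEAREST))
    return (out > MASK_THRESHOLD).astype(np.uint8)


def resize_pair(record: SampleRecord, size: int = 256) -> SampleRecord:
    """Bilinear image resize, nearest-neighbour mask resize."""
    if record.image.shape[:2] == (size, size):
        return record
    return replace(
        record,
        image=_resize_image(record.image, (size, size)),
        mask=_resize_mask(record.mask, (size, size)),
    )


# -------------------------------------------------------- augmentation

def _rotate_pair(image, mask, angle):
    rot_image = ndimage.rotate(image, angle, axes=(1, 0), reshape=False,
                               order=1, mode="reflect")
    rot_mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False,
                              order=0, mode="constant", cval=0)
    return np.clip(rot_image, 0.0, 1.0), rot_mask.astype(np.uint8)


def _center_crop(arr, ch, cw):
    h, w = arr.shape[:2]
    top, left = (h - ch) // 2, (w - cw) // 2
    return arr[top: top + ch, left: left + cw]


def augment(record: SampleRecord, spec: AugmentSpec,
            record_index: int = 0) -> list[SampleRecord]:
    """Expand one record into ``spec.variants_per_image`` variants.

    Each variant independently samples its transform chain: a rotation
    (always, angle uniform in ±rotation_max_deg, bilinear for the image
    and nearest for the mask), a centre crop to ``crop_size`` followed by
    a resize back to the original size (probability ``crop_prob``), and a
    Gaussian blur of the image only (probability ``blur_prob``).  The
    chain is seeded per (record, variant), so a fixed spec seed gives
    bit-identical output sets.
    """
    h, w = record.mask.shape
    ch, cw = spec.crop_size
    if ch > h or cw > w:
        raise ValueError(
            f"crop {spec.crop_size} larger than image {(h, w)}"
        )
    variants = []
    for j in range(spec.variants_per_image):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, record_index, j])
        )
        angle = rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg)
        image, mask = _rotate_pair(record.image, record.mask, angle)
        if rng.random() < spec.crop_prob:
            image = _resize_image(_center_crop(image, ch, cw), (h, w))
            mask = _resize_mask(_center_crop(mask, ch, cw), (h, w))
        if rng.random() < spec.blur_prob:
            image = ndimage.gaussian_filter(
                image, sigma=spec.blur_sigma, truncate=1.25, axes=(0, 1)
            )
        variants.append(
            SampleRecord(image=image.astype(np.float32), mask=mask,
                         source_id=f"{record.source_id}/aug{j}",
                         split=record.split)
        )
    return variants


def augment_dataset(records, spec: AugmentSpec) -> list[SampleRecord]:
    """Augment every record; output count is len(records) × variants."""
    out = []
    for i, record in enumerate(records):
        out.extend(augment(record, spec, record_index=i))
    return out


# ------------------------------------------------------------ splitting

def split_dataset(records, spec: SplitSpec = SplitSpec()
                  ) -> tuple[list[SampleRecord], list[SampleRecord], list[SampleRecord]]:
    """Shuffle and partition into train/val/test.

    Val and test sizes are ``round(n·f)``; the remainder goes to train.
    Splitting happens at the source-image level, so augmentation after
    splitting cannot leak variants across subsets.
    """
    records = list(records)
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split 80/10/10")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_val = int(round(n * spec.fractions[1]))
    n_test = int(round(n * spec.fractions[2]))
    n_train = n - n_val - n_test
    out: tuple[list, list, list] = ([], [], [])
    names = ("train", "val", "test")
    bounds = (n_train, n_train + n_val, n)
    start = 0
    for bucket, name, stop in zip(out, names, bounds):
        for idx in order[start:stop]:
            bucket.append(replace(records[idx], split=name))
        start = stop
    return out


# ------------------------------------------------- synthetic generator

def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u * u) / (a * a) + (v * v) / (b * b) <= 1.0


def _mucosa_background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency pink/red texture."""
    base = np.array([0.72, 0.45, 0.40]) + rng.uniform(-0.06, 0.06, 3)
    noise = rng.standard_normal((size, size, 3))
    low = ndimage.gaussian_filter(noise, sigma=(size / 10, size / 10, 0))
    low /= np.abs(low).max() + 1e-9
    fine = ndimage.gaussian_filter(rng.standard_normal((size, size, 3)),
                                   sigma=(1.5, 1.5, 0))
    fine /= np.abs(fine).max() + 1e-9
    image = base + 0.10 * low + 0.03 * fine
    return np.clip(image, 0.0, 1.0)


def synth_generate(n: int, size: int = 256, seed: int = 0
                   ) -> list[SampleRecord]:
    """Generate ``n`` synthetic colonoscopy-like records.

    Each sample carries 1–3 elliptical lesions totalling 5–40% of the
    frame, rendered as a low-contrast hue shift with Gaussian-feathered
    borders, plus specular highlights.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        image = _mucosa_background(size, rng)
        n_lesions = int(rng.integers(1, 4))
        mask = np.zeros((size, size), dtype=bool)
        lesion_alpha = np.zeros((size, size), dtype=np.float64)
        for _ in range(n_lesions):
            frac = rng.uniform(0.05, 0.40 / n_lesions)
            area = frac * size * size
            ratio = rng.uniform(0.5, 1.0)
            a = math.sqrt(area / (math.pi * ratio))
            b = a * ratio
            cy = rng.uniform(0.25 * size, 0.75 * size)
            cx = rng.uniform(0.25 * size, 0.75 * size)
            theta = rng.uniform(0, math.pi)
            ellipse = _ellipse_mask(size, cy, cx, a, b, theta)
            mask |= ellipse
            lesion_alpha = np.maximum(lesion_alpha, ellipse.astype(np.float64))
        # blurred borders: feather the blend weight, not the mask
        alpha = ndimage.gaussian_filter(lesion_alpha, sigma=size / 40)
        shift = rng.uniform(-0.10, -0.04) * np.array([0.6, 1.0, 0.8])
        shift += rng.uniform(-0.02, 0.02, 3)
        image = image + alpha[..., None] * shift
        # specular highlight speckles
        for _ in range(int(rng.integers(2, 7))):
            sy, sx = rng.uniform(0, size, 2)
            blob = np.exp(
                -(((np.arange(size) - sy)[:, None] ** 2
                   + ((np.arange(size) - sx)[None, :]) ** 2)
                  / (2 * rng.uniform(1.0, 2.5) ** 2))
            )
            image = image + 0.8 * blob[..., None]
        records.append(
            SampleRecord(
                image=np.clip(image, 0.0, 1.0).astype(np.float32),
                mask=mask.astype(np.uint8),
                source_id=f"synth{seed}_{i:05d}",
            )
        )
    return records
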