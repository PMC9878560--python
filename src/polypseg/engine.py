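"""Training loop, early stopping, checkpointing, inference, YAML config.

The training regime mirrors the protocol the architecture was designed
for: Adam at learning rate 1e-4, mini-batches of 4, up to 300 epochs with
early stopping once validation mDice fails to improve for 50 consecutive
epochs; the checkpoint with the best validation mDice is returned.  All
randomness (shuffling, initialisation, splits) derives from explicit
seeds so runs are reproducible on a single CPU thread.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor
from .backbone import EncoderSpec, HDBSpec
from .blocks import DenseASPPSpec
from .data import AugmentSpec, SampleRecord, SplitSpec
from .losses import LossConfig, total_loss
from .metrics import confusion, dice_coefficient
from .network import NetworkSpec, PolypSegNet

__all__ = [
    "TrainConfig",
    "TrainState",
    "train",
    "predict",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "load_config",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    max_epochs: int = 300
    patience: int = 50
    learning_rate: float = 1e-4
    seed: int = 0
    max_steps: int | None = None  # optional cap on optimizer steps

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.patience >= self.max_epochs and self.max_epochs > 1:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainState:
    epoch: int = 0
    best_val_metric: float = -np.inf
    best_epoch: int = 0
    epochs_since_best: int = 0
    history: list[dict] = field(default_factory=list)
    stopped_early: bool = False


def _to_batches(records: list[SampleRecord]):
    images = np.stack([r.image.transpose(2, 0, 1) for r in records])
    masks = np.stack([r.mask[None].astype(np.float32) for r in records])
    return images.astype(np.float32), masks


def _val_mdice(model: PolypSegNet, images: np.ndarray, masks: np.ndarray,
               batch_size: int) -> float:
    model.eval()
    dices = []
    for start in range(0, len(images), batch_size):
        prob = model(images[start: start + batch_size]).numpy()
        pred = (prob >= 0.5).astype(np.uint8)
        gt = masks[start: start + batch_size].astype(np.uint8)
        for p, g in zip(pred, gt):
            dices.append(dice_coefficient(confusion(p[0], g[0])))
    model.train()
    return float(np.mean(dices))


def train(model: PolypSegNet, train_set: list[SampleRecord],
          val_set: list[SampleRecord], cfg: TrainConfig = TrainConfig(),
          loss_cfg: LossConfig = LossConfig(),
          val_metric_fn=None, progress: bool = False
          ) -> tuple[dict[str, np.ndarray], TrainState]:
    """Optimize the compound Dice+focal loss; return the best-validation
    checkpoint (a state dict) and the training trace.

    ``val_metric_fn(model, val_set) -> float`` may replace the built-in
    validation mDice (used by tests to script early stopping).
    """
    from .nn import Adam  # local import keeps module load light

    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    train_x, train_y = _to_batches(train_set)
    val_x, val_y = _to_batches(val_set)
    if val_metric_fn is None:
        def val_metric_fn(m, _):
            return _val_mdice(m, val_x, val_y, cfg.batch_size)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    state = TrainState()
    best_state = model.state_dict()
    steps = 0
    iterator = range(1, cfg.max_epochs + 1)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="epochs")
    model.train()
    for epoch in iterator:
        order = rng.permutation(len(train_x))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
            idx = order[start: start + cfg.batch_size]
            prob = model(train_x[idx])
            loss = total_loss(prob.values, Tensor(train_y[idx]), loss_cfg)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {steps}: {loss.item()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            steps += 1
            epoch_losses.append(loss.item())
        val_metric = float(val_metric_fn(model, val_set))
        state.epoch = epoch
        state.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
            "val_mdice": val_metric,
            "steps": steps,
        })
        if val_metric > state.best_val_metric:
            state.best_val_metric = val_metric
            state.best_epoch = epoch
            state.epochs_since_best = 0
            best_state = model.state_dict()
        else:
            state.epochs_since_best += 1
        if state.epochs_since_best >= cfg.patience:
            state.stopped_early = True
            break
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
    model.load_state_dict(best_state)
    return best_state, state


# ----------------------------------------------------------- inference

def predict(model: PolypSegNet, records: list[SampleRecord],
            out_dir=None, threshold: float = 0.5, batch_size: int = 4
            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Probability map + binary mask per record; optionally write PNGs.

    Inputs whose size disagrees with the model's input size are resized
    with a warning.  Output files are 8-bit: ``<id>_prob.png`` holds the
    probability map, ``<id>_mask.png`` the thresholded mask.
    """
    from .data import resize_pair

    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    size = model.spec.input_size
    prepared = []
    for record in records:
        if record.mask.shape != (size, size):
            warnings.warn(
                f"{record.source_id or 'input'}: resizing "
                f"{record.mask.shape} -> {(size, size)}"
            )
            record = resize_pair(record, size)
        prepared.append(record)
    model.eval()
    images, _ = _to_batches(prepared)
    outputs = []
    for start in range(0, len(images), batch_size):
        prob = model(images[start: start + batch_size]).numpy()
        for p in prob:
            mask = (p[0] >= threshold).astype(np.uint8)
            outputs.append((p[0].copy(), mask))
    if out_dir is not None:
        from PIL import Image
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for record, (p, m) in zip(prepared, outputs):
            stem = (record.source_id or "sample").replace("/", "_")
            Image.fromarray((p * 255).round().astype(np.uint8)).save(
                out_dir / f"{stem}_prob.png"
            )
            Image.fromarray(m * np.uint8(255)).save(out_dir / f"{stem}_mask.png")
    return outputs


def count_parameters(model) -> int:
    """Total trainable scalars."""
    return model.num_parameters()


# -------------------------------------------------------- checkpointing

def _spec_to_dict(spec: NetworkSpec) -> dict:
    return dataclasses.asdict(spec)


def _spec_from_dict(d: dict) -> NetworkSpec:
    enc = d["encoder"]
    encoder = EncoderSpec(
        stem_channels=tuple(enc["stem_channels"]),
        stages=tuple(HDBSpec(**st) for st in enc["stages"]),
        tap_stages=tuple(enc["tap_stages"]),
    )
    aspp = DenseASPPSpec(
        dilation_rates=tuple(d["aspp"]["dilation_rates"]),
        branch_channels=d["aspp"]["branch_channels"],
        bottleneck_channels=d["aspp"]["bottleneck_channels"],
        out_channels=d["aspp"]["out_channels"],
    )
    return NetworkSpec(
        input_size=d["input_size"], encoder=encoder, aspp=aspp,
        decoder_channels=tuple(d["decoder_channels"]),
        attention_reduction=d.get("attention_reduction", 8),
        seed=d.get("seed", 0),
    )


def save_checkpoint(model: PolypSegNet, path) -> None:
    """Single-file checkpoint: weights + the NetworkSpec snapshot."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__spec__"] = np.frombuffer(
        json.dumps(_spec_to_dict(model.spec)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> PolypSegNet:
    with np.load(Path(path)) as data:
        state = {k: data[k] for k in data.files}
    spec = _spec_from_dict(json.loads(bytes(state.pop("__spec__")).decode()))
    model = PolypSegNet(spec)
    model.load_state_dict(state)
    return model.eval()


# ---------------------------------------------------------- YAML config

def _network_spec_from_config(cfg: dict) -> NetworkSpec:
    net = cfg.get("network", {})
    bb = cfg.get("backbone", {})
    aspp = cfg.get("aspp", {})
    att = cfg.get("attention", {})
    kwargs: dict = {}
    if bb:
        m = bb.get("m", 1.7)
        kwargs["encoder"] = EncoderSpec(
            stem_channels=tuple(bb.get("stem", (32, 64))),
            stages=tuple(
                HDBSpec(n_layers=s["n_layers"], growth_rate=s["k"],
                        multiplier=s.get("m", m),
                        transition_channels=s["t"],
                        downsample=s.get("downsample", False))
                for s in bb["stages"]
            ),
            tap_stages=tuple(bb.get("taps", (0, 2, 3, 4))),
        )
    if aspp:
        kwargs["aspp"] = DenseASPPSpec(
            dilation_rates=tuple(aspp.get("dilations", (3, 6, 12, 18))),
            branch_channels=aspp.get("branch_channels", 256),
            bottleneck_channels=aspp.get("bottleneck_channels", 128),
            out_channels=aspp.get("out_channels", 512),
        )
    if "decoder_channels" in net:
        kwargs["decoder_channels"] = tuple(net["decoder_channels"])
    if "input_size" in net:
        kwargs["input_size"] = net["input_size"]
    if "reduction" in att:
        kwargs["attention_reduction"] = att["reduction"]
    if "seed" in net:
        kwargs["seed"] = net["seed"]
    return NetworkSpec(**kwargs)


def load_config(path) -> dict:
    """Parse a YAML run config into typed spec objects.

    Returns a dict with keys ``network`` (NetworkSpec), ``train``
    (TrainConfig), ``loss`` (LossConfig), ``augment`` (AugmentSpec),
    ``split`` (SplitSpec) and ``data`` (raw data block: paths etc.).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    tr = cfg.get("train", {})
    lo = cfg.get("loss", {})
    da = cfg.get("data", {})
    aug = da.get("augment", {})
    sp = da.get("split", {})
    weights = lo.get("weights", (1.0, 1.0))
    return {
        "network": _network_spec_from_config(cfg),
        "train": TrainConfig(
            batch_size=tr.get("batch_size", 4),
            max_epochs=tr.get("max_epochs", 300),
            patience=tr.get("patience", 50),
            learning_rate=float(tr.get("lr", 1e-4)),
            seed=tr.get("seed", 0),
            max_steps=tr.get("max_steps"),
        ),
        "loss": LossConfig(
            focal_alpha=lo.get("alpha", 0.25),
            focal_gamma=lo.get("gamma", 2.0),
            dice_smooth=lo.get("smooth", 1.0),
            dice_weight=weights[0],
            focal_weight=weights[1],
        ),
        "augment": AugmentSpec(
            crop_size=tuple(aug.get("crop", (160, 160))),
            rotation_max_deg=aug.get("rotation", 30.0),
            blur_sigma=aug.get("blur_sigma", 0.8),
            variants_per_image=aug.get("variants", 20),
            seed=aug.get("seed", 0),
        ),
        "split": SplitSpec(
            fractions=tuple(sp.get("fractions", (0.8, 0.1, 0.1))),
            seed=sp.get("seed", 0),
        ),
        "data": da,
    }
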