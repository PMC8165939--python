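"""Phenotype classification from centroid-cropped time-lapse frames.

Each frame is cropped to a square window centred on its Delta-mask centroid,
labelled with the well's culture condition, and fed to a small convolutional
network with a 1->3 channel adapter and a 2-class softmax head (cross-entropy
loss, Adam optimiser, regular checkpoints). Train/evaluation data are split
at the *well* level: all timepoints of a held-out well stay together, so
temporally adjacent frames of one spheroid can never straddle the split —
the leakage control that makes the accuracy curve honest.

The readout is per-timepoint accuracy over the held-out wells, smoothed
with a 10-timepoint rolling mean. Because the two phenotypes only diverge
once branching begins, early-timepoint accuracy sits at chance and rises as
morphologies separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import Adam, SmallCNN, resize_bilinear
from .delta import SpheroidMask
from .io_plate import FrameSeries, PlateLayout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CropSpec:
    """Square crop geometry; out-of-bounds regions are padded.

    The crop must be large enough to contain the whole spheroid at its final
    size — a crop that sees only the object's interior makes the phenotypes
    indistinguishable. The network downscales to its own input size, so a
    generous crop costs nothing at training time.
    """

    output_size: int = 224
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.output_size < 32:
            raise ValueError("output_size must be >= 32")


@dataclass(frozen=True)
class SplitSpec:
    """Well-level hold-out: n complete wells per group, chosen by seed."""

    n_holdout_wells_per_group: int = 4
    seed: int = 0


@dataclass(frozen=True)
class AugmentConfig:
    flip: bool = True
    random_crop: bool = True
    resize: bool = True
    crop_fraction: float = 0.875


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    input_channels: int = 1
    n_classes: int = 2
    learning_rate: float = 2e-3
    batch_size: int = 32
    epochs: int = 10
    checkpoint_every: int = 200
    input_size: int = 96  # crops are bilinearly resized to this side length
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_channels != 1:
            raise ValueError("the classifier accepts single-channel grayscale input")
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three 2x2 pools)")


@dataclass
class CropDataset:
    """Flat collection of cropped images with well/timepoint provenance."""

    images: np.ndarray  # (N, H, W) float32 in [0, 1]
    labels: np.ndarray  # (N,) int class indices
    wells: np.ndarray  # (N,) str
    timepoints: np.ndarray  # (N,) int
    classes: list[str]  # index -> label name
    n_fallback_crops: int = 0  # crops centred on the image centre (empty mask)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def well_ids(self) -> list[str]:
        return sorted(set(self.wells.tolist()))

    def subset(self, idx: np.ndarray) -> "CropDataset":
        return CropDataset(
            images=self.images[idx],
            labels=self.labels[idx],
            wells=self.wells[idx],
            timepoints=self.timepoints[idx],
            classes=list(self.classes),
        )


@dataclass
class TrainedModel:
    """A fitted classifier plus the provenance needed for safe evaluation."""

    net: SmallCNN
    classes: list[str]
    train_wells: list[str]
    config: ModelConfig
    input_center: float = 0.0  # train-set mean intensity, subtracted on input

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        images = _resize_stack(images, self.config.input_size) - np.float32(self.input_center)
        out = []
        for i in range(0, len(images), batch_size):
            out.append(self.net.forward(images[i : i + batch_size, None, :, :], train=False))
        return np.concatenate(out, axis=0)


@dataclass
class AccuracyCurve:
    """Per-timepoint accuracy over held-out wells, with a rolling mean."""

    timepoints: np.ndarray
    accuracy: np.ndarray
    window: int = 10

    @property
    def rolling(self) -> np.ndarray:
        """Centred rolling mean; edge windows truncated, length preserved."""
        return (
            pd.Series(self.accuracy)
            .rolling(self.window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )


def crop_on_centroid(
    frame: np.ndarray, mask: SpheroidMask, spec: CropSpec = CropSpec()
) -> np.ndarray:
    """Cut a square window centred on the mask centroid, rescaled to [0, 1].

    An empty mask falls back to the image centre (the caller should count
    such crops). Out-of-bounds regions are filled with ``pad_value``.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    if mask.empty or mask.centroid is None:
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        cr, cc = mask.centroid
    if np.issubdtype(frame.dtype, np.integer):
        scale = float(np.iinfo(frame.dtype).max)
    else:
        scale = 1.0
    img = frame.astype(np.float32) / scale

    size = spec.output_size
    r0 = int(round(cr)) - size // 2
    c0 = int(round(cc)) - size // 2
    out = np.full((size, size), np.float32(spec.pad_value))
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = img[rs:re, cs:ce]
    return out


def build_dataset(
    series_list: list[FrameSeries],
    masks_by_well: dict[str, list[SpheroidMask]],
    layout: PlateLayout,
    spec: CropSpec = CropSpec(),
    source: str = "frame",
) -> CropDataset:
    """Crop every segmented timepoint of every well into one dataset.

    ``source`` selects what is cropped: the raw frame at the mask's
    timepoint (default) or the Delta-mask silhouette itself
    (``source="mask"``), both guided by the Delta centroid.
    """
    if source not in ("frame", "mask"):
        raise ValueError(f"unknown crop source {source!r}")
    classes = layout.condition_labels
    if len(classes) != 2:
        raise ValueError(f"classification expects exactly 2 conditions, got {classes}")
    images, labels, wells, tps = [], [], [], []
    n_fallback = 0
    for series in series_list:
        cond = layout.condition_of(series.well_id)
        for m in masks_by_well[series.well_id]:
            if source == "frame":
                src = series.frame_at(m.timepoint)
            else:
                src = (m.mask * np.uint8(255)).astype(np.uint8)
            images.append(crop_on_centroid(src, m, spec))
            labels.append(classes.index(cond))
            wells.append(series.well_id)
            tps.append(m.timepoint)
            if m.empty:
                n_fallback += 1
    return CropDataset(
        images=np.stack(images).astype(np.float32),
        labels=np.array(labels, dtype=np.int64),
        wells=np.array(wells),
        timepoints=np.array(tps, dtype=np.int64),
        classes=classes,
        n_fallback_crops=n_fallback,
    )


def split_by_well(
    dataset: CropDataset, layout: PlateLayout, spec: SplitSpec = SplitSpec()
) -> tuple[CropDataset, CropDataset]:
    """Hold out n complete wells per treatment group, selected at random.

    The split is decided at the well level, never the image level, and is
    deterministic given the seed. Raises if a group has too few wells.
    """
    present = set(dataset.wells.tolist())
    rng = np.random.default_rng(spec.seed)
    eval_wells: list[str] = []
    for condition in layout.condition_labels:
        group = sorted(w for w in layout.wells_for(condition) if w in present)
        if len(group) <= spec.n_holdout_wells_per_group:
            raise ValueError(
                f"group {condition!r} has {len(group)} wells; cannot hold out "
                f"{spec.n_holdout_wells_per_group} and still train"
            )
        chosen = rng.choice(len(group), size=spec.n_holdout_wells_per_group, replace=False)
        eval_wells.extend(group[i] for i in sorted(chosen))
    eval_set = set(eval_wells)
    is_eval = np.isin(dataset.wells, sorted(eval_set))
    train_ds = dataset.subset(~is_eval)
    eval_ds = dataset.subset(is_eval)
    assert not set(train_ds.wells) & set(eval_ds.wells)
    return train_ds, eval_ds


def augment(
    image: np.ndarray, rng: np.random.Generator, config: AugmentConfig = AugmentConfig()
) -> np.ndarray:
    """Training-time augmentation: random flips, random crop, resize back.

    With every option disabled this is the identity. Output shape always
    equals input shape. Evaluation must not call this.
    """
    out = image
    if config.flip:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if config.random_crop:
        h, w = out.shape
        ch = max(1, int(round(h * config.crop_fraction)))
        cw = max(1, int(round(w * config.crop_fraction)))
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        cropped = out[r0 : r0 + ch, c0 : c0 + cw]
        if config.resize:
            out = resize_bilinear(np.ascontiguousarray(cropped, dtype=np.float32), (h, w))
        else:
            # keep shape contract without interpolation: pad back
            padded = np.zeros_like(out)
            padded[:ch, :cw] = cropped
            out = padded
    return np.ascontiguousarray(out)


def _resize_stack(images: np.ndarray, size: int) -> np.ndarray:
    """Bilinearly resize a (N, H, W) stack to (N, size, size) if needed."""
    if images.shape[1:] == (size, size):
        return images
    return np.stack([resize_bilinear(im, (size, size)) for im in images])


def train(
    train_ds: CropDataset, config: ModelConfig = ModelConfig()
) -> tuple[TrainedModel, list[tuple[int, dict[str, np.ndarray]]]]:
    """Fit the classifier by mini-batch Adam on cross-entropy.

    Fully seeded: weight init, shuffling and augmentation all derive from
    ``config.seed``. Weights are checkpointed every ``checkpoint_every``
    steps (and at the end); the checkpoint list is returned alongside the
    final model.
    """
    present = np.unique(train_ds.labels)
    if len(present) < 2:
        raise ValueError("training set contains a single class; need both phenotypes")
    ss = np.random.SeedSequence(config.seed)
    s_init, s_shuffle, s_aug = ss.spawn(3)
    net = SmallCNN(n_classes=config.n_classes, seed=int(s_init.generate_state(1)[0] % 2**31))
    rng_shuffle = np.random.default_rng(s_shuffle)
    rng_aug = np.random.default_rng(s_aug)
    opt = Adam(net, lr=config.learning_rate)

    images = _resize_stack(train_ds.images, config.input_size)
    # centre on the train-set mean: removes the large constant background
    # term so early gradients are driven by shape contrast, not brightness
    center = float(images.mean())
    images = images - np.float32(center)
    n = len(train_ds)
    step = 0
    checkpoints: list[tuple[int, dict[str, np.ndarray]]] = []
    do_aug = config.augmentation.flip or config.augmentation.random_crop
    for epoch in range(config.epochs):
        order = rng_shuffle.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = images[idx]
            if do_aug:
                batch = np.stack([augment(im, rng_aug, config.augmentation) for im in batch])
            probs = net.forward(batch[:, None, :, :], train=True)
            loss = net.backward(probs, train_ds.labels[idx])
            opt.step()
            losses.append(loss)
            step += 1
            if config.checkpoint_every > 0 and step % config.checkpoint_every == 0:
                checkpoints.append((step, net.snapshot()))
        logger.info("epoch %d/%d mean loss %.4f", epoch + 1, config.epochs, np.mean(losses))
    checkpoints.append((step, net.snapshot()))
    model = TrainedModel(
        net=net,
        classes=list(train_ds.classes),
        train_wells=train_ds.well_ids,
        config=config,
        input_center=center,
    )
    return model, checkpoints


def save_model(model: TrainedModel, directory) -> None:
    """Persist weights (npz) and run metadata (json) to a model directory."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.net.parameters())
    meta = {
        "classes": model.classes,
        "train_wells": model.train_wells,
        "config": asdict(model.config),
        "input_center": model.input_center,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> TrainedModel:
    """Load a model directory written by :func:`save_model`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    cfg_d = dict(meta["config"])
    cfg_d["augmentation"] = AugmentConfig(**cfg_d["augmentation"])
    config = ModelConfig(**cfg_d)
    net = SmallCNN(n_classes=config.n_classes, seed=0)
    with np.load(directory / "weights.npz") as z:
        net.set_parameters({k: z[k] for k in z.files})
    return TrainedModel(
        net=net,
        classes=list(meta["classes"]),
        train_wells=list(meta["train_wells"]),
        config=config,
        input_center=float(meta.get("input_center", 0.0)),
    )


def evaluate(
    model: TrainedModel, eval_ds: CropDataset, window: int = 10
) -> tuple[pd.DataFrame, AccuracyCurve]:
    """Score held-out wells: per-image probabilities and the accuracy curve.

    Applies no augmentation. Hard-checks the anti-leakage rule: any overlap
    between the model's training wells and the evaluation wells raises.
    """
    overlap = set(model.train_wells) & set(eval_ds.wells.tolist())
    if overlap:
        raise ValueError(f"train/eval well overlap detected: {sorted(overlap)}")
    probs = model.predict_proba(eval_ds.images)
    pred_idx = probs.argmax(axis=1)
    classes = model.classes
    df = pd.DataFrame(
        {
            "well": eval_ds.wells,
            "timepoint": eval_ds.timepoints,
            f"p_{classes[0]}": probs[:, 0],
            f"p_{classes[1]}": probs[:, 1],
            "predicted": [classes[i] for i in pred_idx],
            "actual": [eval_ds.classes[i] for i in eval_ds.labels],
        }
    )
    correct = pred_idx == eval_ds.labels
    tps = np.sort(np.unique(eval_ds.timepoints))
    acc = np.array([correct[eval_ds.timepoints == tp].mean() for tp in tps])
    return df, AccuracyCurve(timepoints=tps, accuracy=acc, window=window)
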