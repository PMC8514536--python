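"""Model training for VCDR regression and glaucoma classification.

Task heads and optimization follow the same recipe for both tasks: Adam at
a base learning rate of 1e-4, multiplied by 0.75 after ten successive
epochs without validation-loss improvement, MSE loss with a linear output
for regression and binary cross-entropy with a sigmoid output for
classification. Augmentation (horizontal mirroring, elastic deformation,
brightness shift, cutout) is applied per image with probability 0.5 each.
A leakage guard refuses any train/val pair sharing a patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .croppolicy import CropSpec
from .nn import Adam, SmallCNN, bce_with_logits_loss, mse_loss, sigmoid

VCDR_REGRESSION = "vcdr"
GLAUCOMA_CLASSIFICATION = "glaucoma"
TASKS = (VCDR_REGRESSION, GLAUCOMA_CLASSIFICATION)

SMALL_CNN = "small_cnn"
RESNET50 = "resnet50"


@dataclass
class AugmentConfig:
    mirror: bool = True
    elastic: bool = True
    brightness: bool = True
    cutout: bool = True
    brightness_range: float = 0.1
    cutout_frac: float = 0.10  # side of the zeroed square, frac of width
    elastic_alpha_frac: float = 8.0 / 512.0  # displacement sd, frac of width
    elastic_sigma_frac: float = 1.0 / 12.0  # smoothing of the field, frac of width

    @property
    def any_enabled(self) -> bool:
        return self.mirror or self.elastic or self.brightness or self.cutout


@dataclass
class TrainConfig:
    task: str = GLAUCOMA_CLASSIFICATION
    base_lr: float = 1e-4
    plateau_factor: float = 0.75
    plateau_patience_epochs: int = 10
    max_epochs: int = 60
    early_stop_patience_epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    backbone: str = SMALL_CNN
    widths: tuple = (16, 32, 64, 128)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.backbone not in (SMALL_CNN, RESNET50):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class TrainedModel:
    model: SmallCNN
    task: str
    crop_spec: CropSpec
    config: TrainConfig
    history: pd.DataFrame

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameter arrays (npz) plus a YAML sidecar."""
        import yaml
        from dataclasses import asdict

        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.model.get_state())
        sidecar = {
            "task": self.task,
            "crop_spec": asdict(self.crop_spec),
            "train_config": asdict(self.config),
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
        self.history.to_csv(path.with_suffix(".history.csv"), index=False)


def build_model(config: TrainConfig) -> SmallCNN:
    """Untrained backbone for the configured task.

    Only the desk-scale SMALL_CNN backbone is implemented; the full-scale
    ImageNet-pretrained ResNet-50 configuration is exposed for completeness
    but requires a GPU deep-learning stack this package does not ship.
    """
    if config.backbone == RESNET50:
        raise NotImplementedError(
            "the ResNet-50 full-scale backbone requires an external deep-learning "
            "framework; use backbone='small_cnn'"
        )
    return SmallCNN(in_channels=3, widths=config.widths, seed=config.seed)


class PlateauScheduler:
    """Multiply lr by ``factor`` after ``patience`` successive epochs without
    validation-loss improvement. The lr is only ever decreased."""

    def __init__(self, base_lr: float, factor: float, patience: int):
        self.lr = base_lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
        return self.lr


def augment(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply each enabled transform with probability 0.5 (HxWx3 array in, same out)."""
    out = image
    h, w = image.shape[:2]
    if config.mirror and rng.random() < 0.5:
        out = out[:, ::-1, :]
    if config.elastic and rng.random() < 0.5:
        alpha = config.elastic_alpha_frac * w
        sigma = config.elastic_sigma_frac * w
        dr = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
        dc = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
        for f in (dr, dc):
            sd = f.std()
            if sd > 0:
                f *= alpha / sd
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = [rows + dr, cols + dc]
        warped = np.empty_like(out, dtype=np.float32)
        for ch in range(out.shape[2]):
            warped[:, :, ch] = ndimage.map_coordinates(
                out[:, :, ch], coords, order=1, mode="reflect"
            )
        out = warped
    if config.brightness and rng.random() < 0.5:
        out = np.clip(out + rng.uniform(-config.brightness_range, config.brightness_range), 0.0, 1.0)
    if config.cutout and rng.random() < 0.5:
        side = max(1, int(round(config.cutout_frac * w)))
        r0 = int(rng.integers(0, h - side + 1))
        c0 = int(rng.integers(0, w - side + 1))
        out = np.array(out, dtype=np.float32, copy=True)
        out[r0 : r0 + side, c0 : c0 + side, :] = 0.0
    return np.ascontiguousarray(out, dtype=np.float32)


def _check_leakage(train_patients: Sequence, val_patients: Sequence) -> None:
    overlap = set(train_patients) & set(val_patients)
    if overlap:
        raise ValueError(
            f"patient-level leakage between splits: {len(overlap)} shared patient ids"
        )


def train(
    model: SmallCNN,
    train_images: np.ndarray,
    train_targets: np.ndarray,
    val_images: np.ndarray,
    val_targets: np.ndarray,
    config: TrainConfig,
    crop_spec: CropSpec = CropSpec(),
    train_patients: Optional[Sequence] = None,
    val_patients: Optional[Sequence] = None,
    verbose: bool = False,
) -> TrainedModel:
    """Minimize the task loss; return the best-validation-loss parameters.

    ``train_images`` / ``val_images`` are N x H x W x 3 float arrays already
    preprocessed (and crop-applied, when the experiment retrains on cropped
    images). Deterministic under ``config.seed``.
    """
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation splits must be non-empty")
    if train_patients is not None and val_patients is not None:
        _check_leakage(train_patients, val_patients)

    loss_fn = mse_loss if config.task == VCDR_REGRESSION else bce_with_logits_loss
    y_train = np.asarray(train_targets, dtype=np.float32)
    y_val = np.asarray(val_targets, dtype=np.float32)
    sched = PlateauScheduler(config.base_lr, config.plateau_factor, config.plateau_patience_epochs)
    opt = Adam(lr=sched.lr)
    rng = np.random.default_rng(config.seed)

    best_val = np.inf
    best_state = model.get_state()
    stale = 0
    records = []
    n = len(train_images)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = train_images[idx]
            if config.augmentation.any_enabled:
                batch = np.stack([augment(im, config.augmentation, rng) for im in batch])
            out = model.forward(batch, keep_cache=True)
            loss, dout = loss_fn(out, y_train[idx])
            _, grads = model.backward(dout)
            model.apply_grads(grads, opt)
            epoch_loss += loss
            n_batches += 1

        val_out = _forward_batched(model, val_images, config.batch_size)
        val_loss, _ = loss_fn(val_out, y_val)
        opt.lr = sched.update(val_loss)
        records.append(
            dict(epoch=epoch, train_loss=epoch_loss / max(n_batches, 1), val_loss=val_loss, lr=opt.lr)
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {records[-1]['train_loss']:.4f}  val {val_loss:.4f}  lr {opt.lr:.2e}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience_epochs:
                break

    model.set_state(best_state)
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "val_loss", "lr"])
    return TrainedModel(model=model, task=config.task, crop_spec=crop_spec, config=config, history=history)


def _forward_batched(model: SmallCNN, images: np.ndarray, batch_size: int) -> np.ndarray:
    outs = []
    for start in range(0, len(images), batch_size):
        outs.append(model.forward(images[start : start + batch_size], keep_cache=False))
    return np.concatenate(outs)


def predict(trained: TrainedModel | SmallCNN, images: np.ndarray, batch_size: int = 64,
            task: Optional[str] = None) -> np.ndarray:
    """Per-image scores in [0, 1]: sigmoid probability for classification,
    clipped value for regression. Batch order preserved; invariant to batch
    partitioning."""
    if isinstance(trained, TrainedModel):
        model, task = trained.model, trained.task
    else:
        model = trained
        if task is None:
            raise ValueError("task required when passing a bare model")
    raw = _forward_batched(model, np.asarray(images, dtype=np.float32), batch_size)
    if task == GLAUCOMA_CLASSIFICATION:
        return sigmoid(raw)
    return np.clip(raw, 0.0, 1.0)
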