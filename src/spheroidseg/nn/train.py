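"""Training loop: mini-batches, 1-cycle LR, validation-JCD early stopping.

Training items are ``(image, target, spheroid_id)`` triples with a
16- or 8-bit :class:`~spheroidseg.io.GrayImage` and a boolean target
mask on the same grid.  The monitored metric is the mean Jaccard
distance of the *postprocessed* validation predictions (threshold →
largest component), i.e. exactly the quantity the segmentation is
judged by, not the raw loss.  The weights of the best-JCD epoch are
restored on stop.

Spheroid identity is the leakage boundary: a spheroid id occurring in
both the training and validation sets aborts before the first epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ..evaluation import jcd
from ..io import GrayImage, apply_transform, resize_image, resize_mask, to_8bit
from ..postprocess import extract_spheroid
from .losses import loss_and_grad
from .model import UNet, predict_probmap
from .optim import make_optimizer
from .schedule import one_cycle_schedule

__all__ = ["TrainConfig", "TrainHistory", "train", "validation_jcd"]

TrainItem = tuple[GrayImage, np.ndarray, str]


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "dice"  # dice | ce | focal
    focal_gamma: float = 2.0
    optimizer: str = "adam"  # adam | radam_lookahead
    lr_bounds: tuple[float, float] = (1e-3, 1e-2)
    epochs: int = 40
    patience: int = 10
    batch_size: int = 2
    seed: int = 0
    augment: bool = True
    resize_factor: float = 1.0

    def __post_init__(self):
        if not 0 < self.lr_bounds[0] < self.lr_bounds[1]:
            raise ValueError("lr_bounds must satisfy 0 < min < max")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


@dataclass
class TrainHistory:
    rows: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_jcd: float = float("inf")
    train_ids: frozenset = frozenset()
    val_ids: frozenset = frozenset()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _prepare(items: Sequence[TrainItem], resize_factor: float):
    """Items → normalized float32 batch arrays at training resolution."""
    xs, ys = [], []
    for image, mask, _sid in items:
        img8 = to_8bit(image)
        if resize_factor != 1.0:
            img8 = resize_image(img8, resize_factor)
            mask = resize_mask(mask, resize_factor)
        xs.append(img8.values.astype(np.float32) / 255.0)
        ys.append(np.asarray(mask, dtype=bool))
    return np.stack(xs)[..., None], np.stack(ys)


def validation_jcd(
    model: UNet, val_set: Sequence[TrainItem], resize_factor: float
) -> float:
    """Mean postprocessed Jaccard distance over a validation set."""
    vals = []
    for image, target, _sid in val_set:
        pm = predict_probmap(model, image, resize_factor)
        seg = extract_spheroid(pm.values)
        vals.append(jcd(seg.spheroid_mask, target))
    return float(np.mean(vals))


def train(
    model: UNet,
    train_set: Sequence[TrainItem],
    val_set: Sequence[TrainItem],
    config: TrainConfig,
    val_metric: Callable[[UNet], float] | None = None,
) -> TrainHistory:
    """Train in place; returns the per-epoch history.

    ``val_metric`` overrides the validation evaluator (used for
    contract tests of the early-stopping logic); by default the mean
    validation JCD through the full postprocessing chain is used.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    train_ids = frozenset(sid for _, _, sid in train_set)
    val_ids = frozenset(sid for _, _, sid in val_set)
    shared = train_ids & val_ids
    if shared:
        raise ValueError(f"data leakage: spheroid ids in both sets: {sorted(shared)}")

    rng = np.random.default_rng(config.seed)

    items = list(train_set)
    if config.augment:
        # one fixed augmented copy per original, doubling the set
        from ..io import AUGMENT_TRANSFORMS

        for image, mask, sid in list(items):
            t = AUGMENT_TRANSFORMS[int(rng.integers(len(AUGMENT_TRANSFORMS)))]
            img_t = GrayImage(
                values=apply_transform(image.values, t),
                bit_depth=image.bit_depth,
                pixel_size=image.pixel_size,
            )
            items.append((img_t, apply_transform(np.asarray(mask, dtype=bool), t), sid))

    X, Y = _prepare(items, config.resize_factor)
    n = len(X)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    lr_of = one_cycle_schedule(config.lr_bounds, total_steps)
    optimizer = make_optimizer(config.optimizer, model.parameters())

    history = TrainHistory(train_ids=train_ids, val_ids=val_ids)
    best_state = model.state_dict()
    since_improve = 0
    step = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        lr = config.lr_bounds[0]
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            model.zero_grad()
            logits = model.forward(X[idx])
            loss, dlogits = loss_and_grad(
                config.loss, logits, Y[idx], gamma=config.focal_gamma
            )
            model.backward(dlogits)
            lr = lr_of(step)
            optimizer.step(model.gradients(), lr)
            step += 1
            losses.append(loss)
        model.trained = True

        if val_metric is not None:
            vj = float(val_metric(model))
        else:
            vj = validation_jcd(model, val_set, config.resize_factor)
        history.rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_jcd": vj,
                "lr": lr,
            }
        )
        if vj < history.best_val_jcd:
            history.best_val_jcd = vj
            history.best_epoch = epoch
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    model.load_state_dict(best_state)
    return history
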