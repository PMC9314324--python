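"""Training loop: AdamW, per-sample cross-entropy, gradient-norm clipping.

Defaults mirror the reference recipe: batch size 64, learning rate 0.001,
gradient L2 norm clipped to 1.0, no weight decay, 70 epochs (reduce via
``TrainConfig`` for desk-scale runs).  The checkpoint with the best
validation detection F1 is retained.
"""

from __future__ import annotations

import copy
import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._layers import Param, cross_entropy
from .model import QrsSegmenter

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "AdamW", "clip_grad_l2", "train", "TrainHistory"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-3
    grad_clip_l2: float = 1.0
    weight_decay: float = 0.0
    epochs: int = 70
    steps_per_epoch: int | None = None  # default: ceil(n_records / batch)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.learning_rate, self.grad_clip_l2,
               self.epochs) <= 0:
            raise ValueError("batch_size, learning_rate, grad_clip_l2 and "
                             "epochs must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


class AdamW:
    """AdamW with decoupled weight decay (decay 0 by default)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_grad_l2(params: list[Param], max_norm: float = 1.0) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
    return norm


@dataclass
class TrainHistory:
    epochs: list[dict]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "train_loss", "val_loss", "val_f1"]
            )
            writer.writeheader()
            for row in self.epochs:
                writer.writerow(
                    {k: row.get(k, "") for k in ("epoch", "train_loss",
                                                 "val_loss", "val_f1")}
                )


def train(
    model: QrsSegmenter,
    train_sampler,
    validation_set: list | None,
    config: TrainConfig,
) -> tuple[QrsSegmenter, TrainHistory]:
    """Train the model on batches drawn from ``train_sampler``.

    ``train_sampler`` must expose ``sample_batch(batch_size) ->
    (signals (B,1,L), targets (B,L))`` and ``__len__`` (record count);
    augmentation happens inside the sampler on every draw.
    ``validation_set`` is a list of (AnnotatedRecord at any fs) used for the
    per-epoch validation loss and detection F1; the best-F1 checkpoint is
    restored before returning.
    """
    if len(train_sampler) == 0:
        raise ValueError("empty training dataset")
    params = model.params()
    optimizer = AdamW(params, lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    steps = config.steps_per_epoch or max(
        1, int(np.ceil(len(train_sampler) / config.batch_size))
    )

    history: list[dict] = []
    best_f1 = -1.0
    best_state = None
    for epoch in range(1, config.epochs + 1):
        losses = []
        for _ in range(steps):
            signals, targets = train_sampler.sample_batch(config.batch_size)
            logits = model.forward(signals, train=True)
            loss, dlogits = cross_entropy(logits, targets)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            model.zero_grad()
            model.backward(dlogits)
            clip_grad_l2(params, config.grad_clip_l2)
            optimizer.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if validation_set:
            val_loss, val_f1 = _validate(model, validation_set)
            row["val_loss"] = val_loss
            row["val_f1"] = val_f1
            if val_f1 > best_f1:
                best_f1 = val_f1
                best_state = copy.deepcopy(model.state_dict())
        history.append(row)
        logger.info("epoch %d: %s", epoch, row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, TrainHistory(epochs=history)


def _validate(model: QrsSegmenter, records: list) -> tuple[float, float]:
    """Deterministic first-30 s validation loss + detection F1."""
    from .. import evaluation, postprocessing, preprocessing
    from .model import infer

    losses = []
    tp = fp = fn = 0
    for annotated in records:
        resampled = preprocessing.resample_to_100hz(annotated)
        model_input, target = preprocessing.validation_window(resampled)
        logits = model.forward(model_input.signal.reshape(1, 1, -1), train=False)
        loss, _ = cross_entropy(logits, target.reshape(1, -1))
        losses.append(loss)
        mask = infer(model, model_input.signal)
        peaks = postprocessing.mask_to_peaks(mask)
        pred_times = sorted(p.center_index / 100.0 for p in peaks)
        ref_times = [
            a.sample_index / 100.0
            for a in resampled.annotations
            if a.sample_index < preprocessing.WINDOW_SAMPLES
        ]
        match = evaluation.match_beats(pred_times, ref_times)
        tp += match.tp
        fp += match.fp
        fn += match.fn
    f1 = 1.0 if (tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return float(np.mean(losses)), float(f1)
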