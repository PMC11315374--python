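"""Training and evaluation driver.

The optimisation protocol splits the model parameters into two labelled
groups — the backbone encoders, and everything added on top of them (fusion
blocks, projections, heads) — each with its own learning rate, and trains
with SGD (momentum, L2 weight decay) under per-branch cross-entropy deep
supervision.  The split exists because the backbone group is typically
initialised from pretrained weights and only fine-tuned (small rate) while
the new modules train from scratch (larger rate); when everything trains
from scratch the two rates are simply set equal and higher.

Each epoch logs training loss and validation Acc/Pre/Rec/F1; the checkpoint
with the best validation accuracy is retained.  Every source of randomness
(shuffling, augmentation) derives from the config seed, so a run is exactly
reproducible on one device.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics as metrics_mod
from .data import LabeledImageSet, augment, images_to_array
from .errors import ConfigurationError, DataError
from .network import LGNet, LGNetConfig, lgnet_loss, predict
from .nn import SGD
from .tensor import Tensor

__all__ = ["TrainConfig", "TrainResult", "build_param_groups", "train",
           "evaluate", "toy_train_config"]


@dataclass(frozen=True)
class TrainConfig:
    backbone_lr: float = 2e-5       # fine-tuning rate for pretrained encoders
    new_param_lr: float = 2e-4      # rate for modules trained from scratch
    momentum: float = 0.9
    weight_decay: float = 5e-6
    batch_size: int = 32
    epochs: int = 80
    seed: int = 0
    lr_schedule: str = "constant"   # or "cosine"
    augment: bool = True
    max_rotation: float = 30.0
    stop_at_val_accuracy: float | None = None

    def __post_init__(self):
        if min(self.backbone_lr, self.new_param_lr, self.momentum,
               self.weight_decay) < 0:
            raise ConfigurationError("rates, momentum and decay must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ConfigurationError(f"unknown schedule {self.lr_schedule!r}")


def toy_train_config(**overrides) -> TrainConfig:
    """From-scratch settings for the small synthetic benchmark: no pretrained
    encoders exist, so both parameter groups share one larger rate."""
    base = dict(backbone_lr=0.02, new_param_lr=0.02, epochs=30,
                weight_decay=5e-6, batch_size=32)
    base.update(overrides)
    return TrainConfig(**base)


BACKBONE_PREFIXES = ("local_encoder.", "global_encoder.")


def build_param_groups(model: LGNet, cfg: TrainConfig) -> list[dict]:
    """Two disjoint, exhaustive groups: backbone encoders vs. new modules."""
    named = list(model.named_parameters())
    backbone = [(n, p) for n, p in named if n.startswith(BACKBONE_PREFIXES)]
    new = [(n, p) for n, p in named if not n.startswith(BACKBONE_PREFIXES)]
    assigned = {n for n, _ in backbone} | {n for n, _ in new}
    missing = [n for n, _ in named if n not in assigned]
    if missing or len(backbone) + len(new) != len(named):
        raise RuntimeError(f"parameters left unassigned to a group: {missing}")
    return [
        {"name": "backbone", "params": backbone, "lr": cfg.backbone_lr},
        {"name": "new_modules", "params": new, "lr": cfg.new_param_lr},
    ]


@dataclass
class TrainResult:
    history: list[dict]
    best_epoch: int
    best_val_accuracy: float
    best_state: dict
    norm_mean: np.ndarray
    norm_std: np.ndarray
    steps: int


def _normalise(batch: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (batch - mean[None, :, None, None]) / std[None, :, None, None]


def _forward_in_batches(model: LGNet, images: np.ndarray, batch_size: int):
    """Eval-mode logits over a NCHW array, batched; returns per-branch arrays."""
    outs: dict[str, list[np.ndarray]] = {}
    for start in range(0, len(images), batch_size):
        logits = model(Tensor(images[start:start + batch_size]))
        for name, lg in logits.items():
            outs.setdefault(name, []).append(lg.data)
    return {name: Tensor(np.concatenate(chunks)) for name, chunks in outs.items()}


def evaluate(model: LGNet, dataset: LabeledImageSet, norm_mean, norm_std,
             batch_size: int = 64, averaging: str = "macro"):
    """Deterministic metrics + per-image predictions for one split."""
    if len(dataset.vocabulary) != model.cfg.num_classes:
        raise ConfigurationError(
            f"model has {model.cfg.num_classes} classes but dataset vocabulary "
            f"has {len(dataset.vocabulary)}: {dataset.vocabulary}")
    model.eval()
    images = _normalise(images_to_array(dataset.records),
                        np.asarray(norm_mean, dtype=np.float32),
                        np.asarray(norm_std, dtype=np.float32))
    labels = dataset.labels()
    logits = _forward_in_batches(model, images, batch_size)
    preds, probs = predict(logits, model.cfg.inference_aggregation)
    counts = metrics_mod.confusion(labels, preds, model.cfg.num_classes)
    sc = metrics_mod.scores(counts, averaging=averaging)
    per_branch_acc = {name: float((lg.data.argmax(axis=-1) == labels).mean())
                      for name, lg in logits.items()}
    return sc, preds, probs, per_branch_acc


def train(model: LGNet, dataset: LabeledImageSet, cfg: TrainConfig) -> TrainResult:
    """Run the optimisation protocol on the 'train' split, validating on 'val'."""
    train_set = dataset.subset("train")
    val_set = dataset.subset("val")
    if not train_set.records or not val_set.records:
        raise DataError("both 'train' and 'val' splits must be non-empty")
    if len(dataset.vocabulary) != model.cfg.num_classes:
        raise ConfigurationError(
            f"model expects {model.cfg.num_classes} classes, dataset has "
            f"{len(dataset.vocabulary)}")

    rng = np.random.default_rng(cfg.seed)
    groups = build_param_groups(model, cfg)
    opt = SGD(groups, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    base_lrs = [g["lr"] for g in opt.groups]

    raw_train = [r.load() for r in train_set.records]        # uint8 HWC
    train_labels = train_set.labels()
    as_float = np.stack(raw_train).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
    norm_mean = as_float.mean(axis=(0, 2, 3))
    norm_std = as_float.std(axis=(0, 2, 3)) + 1e-6

    history: list[dict] = []
    best = {"epoch": -1, "acc": -1.0, "state": None}
    steps = 0
    n = len(raw_train)
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            scale = 0.5 * (1 + np.cos(np.pi * epoch / max(1, cfg.epochs - 1)))
            for g, lr0 in zip(opt.groups, base_lrs):
                g["lr"] = lr0 * scale
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cfg.augment:
                imgs = np.stack([augment(raw_train[i], rng, cfg.max_rotation)
                                 for i in idx])
            else:
                imgs = np.stack([raw_train[i] for i in idx])
            batch = imgs.astype(np.float32).transpose(0, 3, 1, 2) / 255.0
            batch = _normalise(batch, norm_mean, norm_std)
            logits = model(Tensor(batch))
            loss, _ = lgnet_loss(logits, train_labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {steps}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            steps += 1
        sc, _, _, per_branch = evaluate(model, val_set, norm_mean, norm_std,
                                        batch_size=max(64, cfg.batch_size))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_accuracy": sc.accuracy, "val_precision": sc.precision,
               "val_recall": sc.recall, "val_f1": sc.f1,
               **{f"val_acc_{k}": v for k, v in per_branch.items()}}
        history.append(row)
        if sc.accuracy > best["acc"]:
            best = {"epoch": epoch, "acc": sc.accuracy,
                    "state": copy.deepcopy(model.state_dict())}
        if (cfg.stop_at_val_accuracy is not None
                and sc.accuracy >= cfg.stop_at_val_accuracy):
            break
    return TrainResult(history=history, best_epoch=best["epoch"],
                       best_val_accuracy=best["acc"], best_state=best["state"],
                       norm_mean=norm_mean.astype(np.float64),
                       norm_std=norm_std.astype(np.float64), steps=steps)
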