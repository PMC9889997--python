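"""Training protocol: AdamW + cross-entropy, linear warm-up then cosine decay.

The learning rate is updated every iteration: a 2-epoch linear warm-up from
``w0 * lr_init`` up to ``lr_init``, then cosine annealing from ``lr_init``
(5e-4) down to ``lr_min`` (5e-5) over the remaining iterations, reaching
``lr_min`` exactly at the final iteration. Batch size defaults to 32.

Images are standardized per channel with statistics computed from the
training split; the statistics are stored with the history so evaluation
uses the same normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import AdamW, no_grad
from .models import Backbone, save_checkpoint
from .synthetic_data import DatasetManifest, load_split

__all__ = ["TrainConfig", "TrainHistory", "lr_at", "train", "evaluate_split"]


@dataclass
class TrainConfig:
    epochs: int = 300
    warmup_epochs: int = 2
    batch_size: int = 32
    lr_init: float = 5e-4
    lr_min: float = 5e-5
    warmup_start_factor: float = 0.01
    weight_decay: float = 0.05
    seed: int = 0
    image_size: int = 224

    def __post_init__(self):
        if self.lr_min >= self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be below epochs")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # dicts: epoch, train_loss, val_accuracy, lr
    train_mean: list = field(default_factory=list)
    train_std: list = field(default_factory=list)

    def append(self, epoch: int, train_loss: float, val_accuracy: float, lr: float):
        self.epochs.append({
            "epoch": epoch, "train_loss": float(train_loss),
            "val_accuracy": float(val_accuracy), "lr": float(lr),
        })

    def to_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = ["epoch,train_loss,val_accuracy,lr"]
        lines += [
            f"{r['epoch']},{r['train_loss']:.6f},{r['val_accuracy']:.6f},{r['lr']:.8g}"
            for r in self.epochs
        ]
        path.write_text("\n".join(lines) + "\n")


def lr_at(iteration: int, iters_per_epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a global iteration index (0-based)."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    warm = cfg.warmup_epochs * iters_per_epoch
    total = cfg.epochs * iters_per_epoch
    if iteration < warm:
        if warm == 1:
            return cfg.lr_init
        frac = iteration / (warm - 1)
        return cfg.lr_init * (cfg.warmup_start_factor + (1 - cfg.warmup_start_factor) * frac)
    t = iteration - warm
    T = total - warm
    if T <= 1:
        return cfg.lr_min
    return cfg.lr_min + 0.5 * (cfg.lr_init - cfg.lr_min) * (1 + math.cos(math.pi * t / (T - 1)))


def _load_arrays(manifest: DatasetManifest, split: str, image_size: int):
    xs, ys = [], []
    for img, label in load_split(manifest, split, image_size):
        xs.append(np.transpose(img, (2, 0, 1)).astype(np.float32) / 255.0)
        ys.append(label)
    if not xs:
        raise ValueError(f"split {split!r} is empty")
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def _standardize(x: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (x - mean.reshape(1, 3, 1, 1)) / std.reshape(1, 3, 1, 1)


def train(model: Backbone, manifest: DatasetManifest, cfg: TrainConfig,
          out_dir: str | Path | None = None, log=None):
    """Train ``model`` on the manifest's train split; returns (model, history).

    Validation accuracy is measured at every epoch end. When ``out_dir`` is
    given, best-validation and last checkpoints plus the history CSV are
    written there.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 1]))
    model.seed_stochastic(cfg.seed ^ 0x5EED)

    x_train, y_train = _load_arrays(manifest, "train", cfg.image_size)
    x_val, y_val = _load_arrays(manifest, "val", cfg.image_size)
    mean = x_train.mean(axis=(0, 2, 3))
    std = x_train.std(axis=(0, 2, 3)) + 1e-6
    x_train = _standardize(x_train, mean, std)
    x_val = _standardize(x_val, mean, std)

    opt = AdamW(model.parameters(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)
    n = len(y_train)
    ipe = max(1, math.ceil(n / cfg.batch_size))
    history = TrainHistory(train_mean=mean.tolist(), train_std=std.tolist())
    best_acc, it = -1.0, 0
    out_dir = Path(out_dir) if out_dir is not None else None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            lr = lr_at(it, ipe, cfg)
            opt.lr = lr
            opt.zero_grad()
            loss = model(x_train[idx]).softmax_cross_entropy(y_train[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at iteration {it} (lr={lr:.3g})"
                )
            loss.backward()
            opt.step()
            losses.append(loss.item())
            it += 1
        val_acc = _accuracy(model, x_val, y_val, cfg.batch_size)
        history.append(epoch + 1, float(np.mean(losses)), val_acc, lr)
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.epochs} loss={np.mean(losses):.4f} "
                f"val_acc={val_acc:.4f} lr={lr:.3g}")
        if out_dir is not None:
            if val_acc > best_acc:
                save_checkpoint(model, out_dir / "best.npz")
            save_checkpoint(model, out_dir / "last.npz")
            history.to_csv(out_dir / "history.csv")
        best_acc = max(best_acc, val_acc)
    return model, history


def _accuracy(model: Backbone, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    model.eval()
    correct = 0
    with no_grad():
        for start in range(0, len(y), batch_size):
            logits = model(x[start : start + batch_size]).data
            correct += int((logits.argmax(axis=1) == y[start : start + batch_size]).sum())
    return correct / len(y)


def evaluate_split(model: Backbone, manifest: DatasetManifest, split: str,
                   image_size: int | None = None, batch_size: int = 32,
                   normalization: tuple | None = None):
    """Evaluation-mode forward over a split in manifest order.

    Returns aligned ``(predictions, labels)`` integer vectors. Pass
    ``normalization=(mean, std)`` (the training-split statistics) for
    results consistent with training; otherwise the split's own statistics
    are used.
    """
    image_size = image_size if image_size is not None else manifest.image_size
    x, y = _load_arrays(manifest, split, image_size)
    if normalization is not None:
        mean, std = (np.asarray(a, dtype=np.float32) for a in normalization)
    else:
        mean, std = x.mean(axis=(0, 2, 3)), x.std(axis=(0, 2, 3)) + 1e-6
    x = _standardize(x, mean, std)
    model.eval()
    preds = []
    with no_grad():
        for start in range(0, len(y), batch_size):
            preds.append(model(x[start : start + batch_size]).data.argmax(axis=1))
    return np.concatenate(preds), y
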