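"""Classification metrics, confusion matrices and Grad-CAM saliency.

Metrics follow the standard confusion-matrix definitions: per class k,
``recall = TP/(TP+FN)``, ``precision = TP/(TP+FP)``,
``F1 = 2TP/(2TP+FP+FN)``; multiclass accuracy is ``trace/total`` (which
reduces to ``(TP+TN)/(P+N)`` for two classes). Single summary values are
macro averages (unweighted class means) — on a class-balanced evaluation
set macro recall coincides exactly with accuracy, matching the pattern in
the published comparison tables. Undefined per-class ratios (zero
denominator) score 0 and are flagged.

Grad-CAM: for a chosen spatial layer with activations ``A_k``, the weights
are ``alpha_k = mean_{h,w} d(logit_c)/dA_k``; the map is
``ReLU(sum_k alpha_k A_k)``, bilinearly upsampled to the input size and
min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .models import Backbone, FEATURE_LAYERS
from .synthetic_data import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "GradCAMMap",
    "confusion_matrix",
    "per_class_counts",
    "metrics",
    "grad_cam",
    "render_overlay",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true class, columns = predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path, class_names=None) -> None:
        names = list(class_names) if class_names is not None else [
            str(i) for i in range(self.n_classes)
        ]
        lines = ["true\\pred," + ",".join(names)]
        for i, row in enumerate(self.counts):
            lines.append(names[i] + "," + ",".join(str(int(v)) for v in row))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class MetricsReport:
    accuracy: float
    precision: list
    recall: list
    f1: list
    macro_precision: float
    macro_recall: float
    macro_f1: float
    zero_division_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "zero_division_flags": self.zero_division_flags,
        }


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """counts[i, j] = number of samples of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes
        or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels out of range [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def per_class_counts(cm: ConfusionMatrix, k: int):
    """(TP, FP, FN, TN) of class ``k`` in one-vs-rest terms."""
    if not 0 <= k < cm.n_classes:
        raise IndexError(f"class index {k} out of range [0, {cm.n_classes})")
    tp = int(cm.counts[k, k])
    fp = int(cm.counts[:, k].sum()) - tp
    fn = int(cm.counts[k, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("cannot compute metrics of an empty confusion matrix")
    precision, recall, f1, flags = [], [], [], []
    for k in range(cm.n_classes):
        tp, fp, fn, _ = per_class_counts(cm, k)
        if tp + fp == 0:
            precision.append(0.0)
            flags.append(f"class {k}: precision undefined (no predicted positives)")
        else:
            precision.append(tp / (tp + fp))
        if tp + fn == 0:
            recall.append(0.0)
            flags.append(f"class {k}: recall undefined (no true positives in set)")
        else:
            recall.append(tp / (tp + fn))
        f1.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return MetricsReport(
        accuracy=float(np.trace(cm.counts)) / cm.total,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(np.mean(precision)),
        macro_recall=float(np.mean(recall)),
        macro_f1=float(np.mean(f1)),
        zero_division_flags=flags,
    )


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------


@dataclass
class GradCAMMap:
    values: np.ndarray  # H x W in [0, 1]
    target_class: int
    source_layer: str
    degenerate: bool = False


def _prepare_input(image: np.ndarray, normalization: tuple | None) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] == 3 and image.dtype == np.uint8:
        x = np.transpose(image, (2, 0, 1)).astype(np.float32) / 255.0
    elif image.ndim == 3 and image.shape[0] == 3:
        x = image.astype(np.float32)
    else:
        raise ValueError(f"expected HxWx3 uint8 or 3xHxW float image, got {image.shape}")
    if normalization is not None:
        mean, std = (np.asarray(a, dtype=np.float32) for a in normalization)
        x = (x - mean.reshape(3, 1, 1)) / std.reshape(3, 1, 1)
    return x[None]


def grad_cam(model: Backbone, image: np.ndarray, target_class: int,
             layer: str = "stage4", normalization: tuple | None = None) -> GradCAMMap:
    """Class-discriminative saliency map for one image.

    ``layer`` names a spatial feature map of the backbone
    (``stem``, ``stage1`` ... ``stage4``).
    """
    if layer not in FEATURE_LAYERS:
        raise ValueError(f"layer {layer!r} has no spatial feature map; "
                         f"choose from {FEATURE_LAYERS}")
    x = _prepare_input(image, normalization)
    H, W = x.shape[2], x.shape[3]
    model.eval()
    logits = model.forward(x, capture=(layer,))
    target_class = int(target_class)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target class {target_class} out of range")
    feats = model.feature(layer)
    logits.narrow(0, 0, 1).narrow(1, target_class, 1).sum().backward()
    if feats.grad is None:
        return GradCAMMap(np.zeros((H, W), dtype=np.float32), target_class, layer, True)
    alpha = feats.grad.mean(axis=(2, 3))                      # (1, C)
    raw = np.maximum((alpha[0][:, None, None] * feats.data[0]).sum(axis=0), 0.0)
    upsampled = np.asarray(
        Image.fromarray(raw.astype(np.float32), mode="F").resize((W, H), Image.BILINEAR)
    )
    peak = float(upsampled.max())
    if peak <= 0.0:
        return GradCAMMap(np.zeros((H, W), dtype=np.float32), target_class, layer, True)
    lo = float(upsampled.min())
    return GradCAMMap(((upsampled - lo) / (peak - lo)).astype(np.float32),
                      target_class, layer, False)


def _colormap(v: np.ndarray) -> np.ndarray:
    """Linear cold-to-warm map: 0 -> blue, 1 -> red."""
    v = np.clip(v, 0.0, 1.0)[..., None]
    warm = np.array([255.0, 0.0, 0.0])
    cold = np.array([0.0, 0.0, 255.0])
    return cold + (warm - cold) * v


def render_overlay(image: np.ndarray, cam: GradCAMMap, alpha: float = 0.5) -> np.ndarray:
    """Blend the color-mapped saliency over the image with opacity ``alpha``."""
    image = np.asarray(image)
    if image.shape[:2] != cam.values.shape:
        raise ValueError(f"image {image.shape[:2]} and map {cam.values.shape} shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    heat = _colormap(cam.values)
    out = (1.0 - alpha) * image.astype(np.float64) + alpha * heat
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
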