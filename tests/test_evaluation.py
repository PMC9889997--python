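"""Metrics, confusion matrices and Grad-CAM saliency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import confusion_matrix as sk_confusion_matrix

from jujubenet.evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    grad_cam,
    metrics,
    per_class_counts,
    render_overlay,
)
from jujubenet.nn import Conv2d, GlobalAvgPool, Linear, Module


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_matrix_hand_examples():
    cm = confusion_matrix([0, 1, 2], [0, 1, 2], 3)
    assert np.array_equal(cm.counts, np.eye(3, dtype=np.int64))
    cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
    assert np.array_equal(cm.counts, [[1, 1], [0, 1]])
    assert np.array_equal(confusion_matrix([], [], 4).counts, np.zeros((4, 4)))


def test_confusion_matrix_matches_sklearn(rng):
    y_true = rng.integers(0, 6, 500)
    y_pred = rng.integers(0, 6, 500)
    ours = confusion_matrix(y_true, y_pred, 6).counts
    ref = sk_confusion_matrix(y_true, y_pred, labels=range(6))
    assert np.array_equal(ours, ref)


def test_confusion_matrix_rejects_bad_labels():
    with pytest.raises(ValueError, match="out of range"):
        confusion_matrix([0, 3], [0, 1], 3)
    with pytest.raises(ValueError, match="mismatch"):
        confusion_matrix([0, 1], [0], 2)


def test_per_class_counts_and_conservation(rng):
    cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
    assert per_class_counts(cm, 0) == (1, 0, 1, 1)
    identity = ConfusionMatrix(np.eye(3, dtype=np.int64))
    for k in range(3):
        assert per_class_counts(identity, k) == (1, 0, 0, 2)
    big = confusion_matrix(rng.integers(0, 4, 200), rng.integers(0, 4, 200), 4)
    for k in range(4):
        assert sum(per_class_counts(big, k)) == big.total


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_metrics_perfect_predictions():
    rep = metrics(ConfusionMatrix(np.diag([5, 5, 5]).astype(np.int64)))
    assert rep.accuracy == rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0


def test_metrics_binary_hand_case():
    # positive class 1: TP=3, FP=1, FN=2, TN=4
    cm = ConfusionMatrix(np.array([[4, 1], [2, 3]], dtype=np.int64))
    rep = metrics(cm)
    assert rep.precision[1] == pytest.approx(0.75)
    assert rep.recall[1] == pytest.approx(0.6)
    assert rep.f1[1] == pytest.approx(6 / 9)
    assert rep.accuracy == pytest.approx(7 / 10)


def test_balanced_set_accuracy_equals_macro_recall(rng):
    # equal class sizes: accuracy == unweighted mean of per-class recalls
    y_true = np.repeat(np.arange(6), 40)
    y_pred = rng.integers(0, 6, y_true.size)
    rep = metrics(confusion_matrix(y_true, y_pred, 6))
    assert rep.accuracy == pytest.approx(rep.macro_recall, abs=1e-12)


@settings(max_examples=60, derandomize=True)
@given(counts=arrays(np.int64, (4, 4), elements=st.integers(0, 50)))
def test_metric_bounds_and_f1_identities(counts):
    if counts.sum() == 0:
        return
    rep = metrics(ConfusionMatrix(counts))
    for vals in (rep.precision, rep.recall, rep.f1, [rep.accuracy, rep.macro_f1]):
        assert all(0.0 <= v <= 1.0 for v in vals)
    for k in range(4):
        tp, fp, fn, _ = per_class_counts(ConfusionMatrix(counts), k)
        if tp + fp + fn:
            assert (rep.f1[k] == 0.0) == (tp == 0)
        if tp + fp and tp + fn and rep.precision[k] + rep.recall[k] > 0:
            harmonic = (2 * rep.precision[k] * rep.recall[k]
                        / (rep.precision[k] + rep.recall[k]))
            assert rep.f1[k] == pytest.approx(harmonic)


def test_metrics_zero_division_flagged():
    cm = ConfusionMatrix(np.array([[3, 0], [2, 0]], dtype=np.int64))
    rep = metrics(cm)
    assert rep.precision[1] == 0.0
    assert any("precision undefined" in f for f in rep.zero_division_flags)
    with pytest.raises(ValueError, match="empty"):
        metrics(ConfusionMatrix(np.zeros((2, 2), dtype=np.int64)))


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

class ToyNet(Module):
    """conv -> GELU -> conv -> GAP -> linear, with a capturable feature map."""

    def __init__(self, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(3, 4, 3, padding=1, rng=rng)
        self.conv2 = Conv2d(4, 4, 3, padding=1, rng=rng)
        self.pool = GlobalAvgPool()
        self.head = Linear(4, 3, rng=rng)
        # non-trivial weights so gradients are informative
        self.head.weight.data = rng.normal(0, 0.5, (4, 3)).astype(np.float32)
        self._features = {}

    def forward(self, x, capture=()):
        from jujubenet.nn import Tensor
        x = Tensor.as_tensor(x)
        f = self.conv1(x)
        if "stem" in capture:
            self._features["stem"] = f
        return self.head(self.pool(self.conv2(f.gelu())))

    def feature(self, name):
        return self._features[name]


def _toy_tail(net, feats):
    """Float64 numpy replay of the toy model after the captured layer."""
    from oracles import naive_conv2d, np_gelu

    y = naive_conv2d(np_gelu(feats), net.conv2.weight.data.astype(np.float64),
                     net.conv2.bias.data.astype(np.float64), padding=1)
    pooled = y.mean(axis=(1, 2))
    return pooled @ net.head.weight.data.astype(np.float64) + net.head.bias.data


def test_grad_cam_matches_finite_difference_oracle(rng):
    net = ToyNet(seed=1).eval()
    img = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
    target = 2
    cam = grad_cam(net, img, target, layer="stem")
    # recompute the map from finite-difference gradients of the tail
    logits = net.forward(np.transpose(img, (2, 0, 1)).astype(np.float32)[None] / 255.0,
                         capture=("stem",))
    A = net.feature("stem").data[0].astype(np.float64)
    eps = 1e-4
    grads = np.zeros_like(A)
    for c in range(A.shape[0]):
        for i in range(A.shape[1]):
            for j in range(A.shape[2]):
                ap, am = A.copy(), A.copy()
                ap[c, i, j] += eps
                am[c, i, j] -= eps
                grads[c, i, j] = (_toy_tail(net, ap)[target] - _toy_tail(net, am)[target]) / (2 * eps)
    alpha = grads.mean(axis=(1, 2))
    raw = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    want = (raw - raw.min()) / (raw.max() - raw.min())
    assert np.abs(cam.values - want).max() <= 1e-3
    assert cam.values.shape == img.shape[:2]
    assert cam.values.min() >= 0.0 and cam.values.max() == pytest.approx(1.0)


def test_grad_cam_linear_readout_of_single_channel(rng):
    # head reads the global average of feature channel 1 only: the map must be
    # proportional to that channel's rectified activation
    net = ToyNet(seed=2).eval()
    net.conv2.weight.data = np.zeros_like(net.conv2.weight.data)
    for c in range(4):  # conv2 = identity (1 at kernel center of own channel)
        net.conv2.weight.data[c, c, 1, 1] = 1.0
    net.conv2.bias.data[:] = 0.0
    net.head.weight.data = np.zeros_like(net.head.weight.data)
    net.head.weight.data[1, 0] = 1.0
    img = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
    cam = grad_cam(net, img, 0, layer="stem")
    logits = net.forward(np.transpose(img, (2, 0, 1)).astype(np.float32)[None] / 255.0,
                         capture=("stem",))
    A1 = net.feature("stem").data[0, 1]
    # d logit0 / d stem = d(gap(gelu(A)_1))/dA; alpha picks channel 1 only, so
    # the normalized map equals normalized relu(alpha_1 * A_1)
    want_raw = np.maximum(cam_weight(net, img) * A1, 0.0)
    want = (want_raw - want_raw.min()) / (want_raw.max() - want_raw.min())
    assert np.allclose(cam.values, want, atol=1e-5)


def cam_weight(net, img):
    """Mean gradient of the target logit w.r.t. stem channel 1 (analytic)."""
    x = np.transpose(img, (2, 0, 1)).astype(np.float32)[None] / 255.0
    logits = net.forward(x, capture=("stem",))
    logits.narrow(0, 0, 1).narrow(1, 0, 1).sum().backward()
    return net.feature("stem").grad[0, 1].mean()


def test_grad_cam_detached_layer_is_degenerate(rng):
    class DetachedNet(ToyNet):
        def forward(self, x, capture=()):
            from jujubenet.nn import Tensor
            x = Tensor.as_tensor(x)
            if "stem" in capture:
                self._features["stem"] = self.conv1(x)  # never feeds the logits
            return self.head(self.pool(self.conv2(x.narrow(1, 0, 3) * 1.0 + 0.0)
                                       .gelu()).narrow(1, 0, 4))

    net = DetachedNet(seed=3).eval()
    net.conv2 = Conv2d(3, 4, 3, padding=1, rng=np.random.default_rng(4))
    img = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
    cam = grad_cam(net, img, 0, layer="stem")
    assert cam.degenerate and not cam.values.any()


def test_grad_cam_rejects_unknown_layer(rng):
    net = ToyNet().eval()
    img = np.zeros((8, 8, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="spatial feature map"):
        grad_cam(net, img, 0, layer="head")


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

def test_overlay_blend_arithmetic(rng):
    img = (rng.random((6, 6, 3)) * 255).astype(np.uint8)
    from jujubenet.evaluation import GradCAMMap
    cam = GradCAMMap(np.ones((6, 6), dtype=np.float32), 0, "stage4")
    assert np.array_equal(render_overlay(img, cam, 0.0), img)
    warm = np.array([255, 0, 0], dtype=np.float64)
    full = render_overlay(img, cam, 1.0)
    assert np.array_equal(full, np.broadcast_to(warm, img.shape).astype(np.uint8))
    half = render_overlay(img, cam, 0.5)
    want = np.clip(np.round(0.5 * img + 0.5 * warm), 0, 255).astype(np.uint8)
    assert np.array_equal(half, want)
    cold = render_overlay(img, GradCAMMap(np.zeros((6, 6), np.float32), 0, "s"), 1.0)
    assert np.array_equal(cold[..., 2], np.full((6, 6), 255, np.uint8))


def test_overlay_shape_mismatch_rejected(rng):
    from jujubenet.evaluation import GradCAMMap
    cam = GradCAMMap(np.ones((4, 4), dtype=np.float32), 0, "stage4")
    with pytest.raises(ValueError, match="shapes differ"):
        render_overlay(np.zeros((6, 6, 3), np.uint8), cam, 0.5)
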