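"""Region heads: ROI-Align pooling, classification softmax, box and mask
branches, and the combined multi-task objective.

The softmax classifier is also exposed as standalone parameter math —
hypothesis function, cost, gradient and the stochastic-gradient update

    p_i = exp(theta_i^T x) / sum_k exp(theta_k^T x)
    J(theta) = -(1/m) sum_i sum_j 1{y_i = j} (theta_j^T x_i - log sum_l exp(theta_l^T x_i))
    dJ/dtheta_j = -(1/m) sum_i [1{y_i = j} - p(y_i = j | x_i)] x_i
    theta_j <- theta_j - alpha dJ/dtheta_j

with labels y in {1..k} and max-subtraction for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .autodiff import Tensor, as_tensor
from .nn import Conv2d, Linear, Module, upsample_nearest
from .synthetic import InstanceLabelMap

__all__ = [
    "RoiFeature", "SoftmaxParams", "DetectionResult",
    "roi_align", "softmax_probs", "softmax_loss", "softmax_gradient",
    "sgd_step", "MaskHead", "ClassBoxHead", "paste_mask",
    "multi_task_loss", "detections_to_label_map",
]

RoiFeature = Tensor  # (R, C, S, S) pooled grids, size independent of the box


# ---------------------------------------------------------------------------
# ROI Align
# ---------------------------------------------------------------------------

def roi_align(features: Tensor, boxes, output_size: int,
              spatial_scale: float = 1.0, samples_per_bin: int = 2) -> Tensor:
    """Pool each box to ``output_size x output_size`` by bilinear sampling.

    ``features`` is a single-image ``(C, H, W)`` map; ``boxes`` are
    half-open image-coordinate boxes scaled into feature coordinates by
    ``spatial_scale``.  Each output bin averages ``samples_per_bin**2``
    regularly spaced bilinear samples; no coordinate is rounded.
    The sampling is linear in the feature map, so the exact adjoint is
    used for the backward pass.
    """
    features = as_tensor(features)
    C, H, W = features.shape
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64)) * spatial_scale
    if len(boxes) == 0:
        return Tensor(np.zeros((0, C, output_size, output_size)))
    if ((boxes[:, 2] - boxes[:, 0]) <= 0).any() or ((boxes[:, 3] - boxes[:, 1]) <= 0).any():
        raise ValueError("degenerate box passed to roi_align")
    S, q = output_size, samples_per_bin
    n = S * q
    # uniform n-point grid with half-sample offsets == q samples per bin
    frac = (np.arange(n) + 0.5) / n
    ys = boxes[:, 1, None] + frac[None, :] * (boxes[:, 3] - boxes[:, 1])[:, None]
    xs = boxes[:, 0, None] + frac[None, :] * (boxes[:, 2] - boxes[:, 0])[:, None]
    # sample coordinates are pixel-center based
    ys = np.clip(ys - 0.5, 0.0, H - 1.0)
    xs = np.clip(xs - 0.5, 0.0, W - 1.0)
    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy = ys - y0
    wx = xs - x0
    R = len(boxes)
    yy0 = np.broadcast_to(y0[:, :, None], (R, n, n))
    yy1 = np.broadcast_to(y1[:, :, None], (R, n, n))
    xx0 = np.broadcast_to(x0[:, None, :], (R, n, n))
    xx1 = np.broadcast_to(x1[:, None, :], (R, n, n))
    wyy = np.broadcast_to(wy[:, :, None], (R, n, n))
    wxx = np.broadcast_to(wx[:, None, :], (R, n, n))
    f = features.data
    samples = ((1 - wyy) * (1 - wxx) * f[:, yy0, xx0] +
               (1 - wyy) * wxx * f[:, yy0, xx1] +
               wyy * (1 - wxx) * f[:, yy1, xx0] +
               wyy * wxx * f[:, yy1, xx1])            # (C, R, n, n)
    pooled = samples.reshape(C, R, S, q, S, q).mean(axis=(3, 5)).transpose(1, 0, 2, 3)
    out = Tensor(pooled, features.requires_grad, parents=(features,))

    def bw(g):
        if not features.requires_grad:
            return
        gs = np.repeat(np.repeat(g.transpose(1, 0, 2, 3), q, axis=2), q, axis=3) / (q * q)
        gf = np.zeros_like(f)
        for wgt, yy, xx in (((1 - wyy) * (1 - wxx), yy0, xx0),
                            ((1 - wyy) * wxx, yy0, xx1),
                            (wyy * (1 - wxx), yy1, xx0),
                            (wyy * wxx, yy1, xx1)):
            np.add.at(gf, (slice(None), yy, xx), wgt * gs)
        features.accumulate(gf)
    out._backward_fn = bw
    return out


# ---------------------------------------------------------------------------
# softmax classifier math
# ---------------------------------------------------------------------------

@dataclass
class SoftmaxParams:
    """Per-class weight vectors theta (k x d) and learning rate alpha."""

    theta: np.ndarray
    alpha: float = 0.01

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 2 or self.theta.shape[0] < 2:
            raise ValueError("theta must be (k >= 2, d)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def k(self) -> int:
        return self.theta.shape[0]


def _logits(x: np.ndarray, params: SoftmaxParams) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return np.atleast_2d(x) @ params.theta.T        # (m, k)


def softmax_probs(x, params: SoftmaxParams) -> np.ndarray:
    """Class probabilities for one sample (d,) or a batch (m, d)."""
    z = _logits(x, params)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    return p[0] if np.asarray(x).ndim == 1 else p


def softmax_loss(X, y, params: SoftmaxParams) -> float:
    """Mean negative log-likelihood; labels ``y`` are 1-based in {1..k}."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    if ((y < 1) | (y > params.k)).any():
        raise ValueError("labels must lie in 1..k")
    z = _logits(X, params)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    correct = z[np.arange(len(y)), y - 1]
    return float(-(correct - lse).mean())


def softmax_gradient(X, y, params: SoftmaxParams) -> np.ndarray:
    """Gradient of the cost per class vector, shape (k, d)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    m = X.shape[0]
    p = softmax_probs(X, params)
    p = np.atleast_2d(p)
    onehot = np.zeros_like(p)
    onehot[np.arange(m), y - 1] = 1.0
    return -(onehot - p).T @ X / m


def sgd_step(params: SoftmaxParams, gradient: np.ndarray,
             alpha: float | None = None) -> SoftmaxParams:
    """One gradient-descent update theta_j <- theta_j - alpha dJ/dtheta_j."""
    a = params.alpha if alpha is None else alpha
    if a <= 0:
        raise ValueError("alpha must be positive")
    return SoftmaxParams(theta=params.theta - a * np.asarray(gradient), alpha=params.alpha)


# ---------------------------------------------------------------------------
# head networks
# ---------------------------------------------------------------------------

class ClassBoxHead(Module):
    """Pooled ROI -> shared fc -> (class logits, per-class box deltas)."""

    def __init__(self, in_channels: int, pooled_size: int = 7,
                 hidden: int = 128, num_classes: int = 2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.num_classes = num_classes
        self.pooled_size = pooled_size
        d = in_channels * pooled_size * pooled_size
        self.fc = Linear(d, hidden, rng=rng)
        self.cls = Linear(hidden, num_classes, rng=rng, init_scale=0.1)
        self.box = Linear(hidden, 4 * num_classes, rng=rng, init_scale=0.1)

    def __call__(self, roi: RoiFeature):
        R = roi.shape[0]
        h = self.fc(roi.reshape(R, -1)).relu()
        return self.cls(h), self.box(h).reshape(R, self.num_classes, 4)


class MaskHead(Module):
    """Small FCN: convs on the pooled ROI, 2x upsampling, per-class logits."""

    def __init__(self, in_channels: int, channels: int = 32,
                 num_classes: int = 2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.num_classes = num_classes
        self.conv1 = Conv2d(in_channels, channels, 3, rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.conv_up = Conv2d(channels, channels, 3, rng=rng)
        self.logits = Conv2d(channels, num_classes, 1, rng=rng, init_scale=0.1)

    def __call__(self, roi: RoiFeature) -> Tensor:
        """(R, C, M/2, M/2) pooled features -> (R, k, M, M) mask logits."""
        h = self.conv1(roi).relu()
        h = self.conv2(h).relu()
        h = self.conv_up(upsample_nearest(h, 2)).relu()
        return self.logits(h)


def paste_mask(mask_prob: np.ndarray, box, image_shape,
               threshold: float = 0.5) -> np.ndarray:
    """Resample an M x M mask probability grid into image coordinates.

    The grid is bilinearly resized to the (rounded) box extent and
    thresholded; returns a boolean H x W image mask.
    """
    H, W = image_shape
    from .rpn import Box as _Box
    if isinstance(box, _Box):
        box = box.as_array()
    x1, y1, x2, y2 = box
    xi1, yi1 = int(np.floor(x1)), int(np.floor(y1))
    xi2, yi2 = int(np.ceil(x2)), int(np.ceil(y2))
    xi1, yi1 = max(0, xi1), max(0, yi1)
    xi2, yi2 = min(W, xi2), min(H, yi2)
    out = np.zeros((H, W), dtype=bool)
    if xi2 <= xi1 or yi2 <= yi1:
        return out
    resized = _sk_resize(np.asarray(mask_prob, dtype=np.float64),
                         (yi2 - yi1, xi2 - xi1), order=1, mode="edge",
                         anti_aliasing=False)
    out[yi1:yi2, xi1:xi2] = resized >= threshold
    return out


@dataclass
class DetectionResult:
    """One detected instance: class, confidence, box and image-frame mask."""

    class_id: int
    score: float
    box: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def detections_to_label_map(results: list[DetectionResult], shape) -> InstanceLabelMap:
    """Resolve overlapping masks by score order into a partition label map."""
    grid = np.zeros(shape, dtype=np.int32)
    ordered = sorted(range(len(results)),
                     key=lambda i: (-results[i].score, i))
    next_id = 1
    for i in ordered:
        fg = results[i].mask & (grid == 0)
        if fg.any():
            grid[fg] = next_id
            next_id += 1
    return InstanceLabelMap(grid)


def multi_task_loss(rpn_terms, cls_loss, box_loss, mask_loss, weights=None):
    """Total training objective: weighted sum of the four terms.

    ``rpn_terms`` may be an :class:`~nucseg.rpn.RpnLossTerms` (its total
    is used) or a scalar.  Default weights are all 1.
    """
    rpn_total = getattr(rpn_terms, "total", rpn_terms)
    terms = [rpn_total, cls_loss, box_loss, mask_loss]
    weights = weights or (1.0, 1.0, 1.0, 1.0)
    total = None
    for w, t in zip(weights, terms):
        wt = t * w if isinstance(t, Tensor) else float(t) * w
        total = wt if total is None else total + wt
    return total
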