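"""Region-proposal machinery: anchors, box parameterization, loss, NMS.

Boxes are axis-aligned, 0-based and half-open: ``[x1, x2) x [y1, y2)``
with center ``(x, y) = ((x1+x2)/2, (y1+y2)/2)`` and size ``(w, h)``.
The regression parameterization against an anchor ``(xa, ya, wa, ha)``
is

    tx = (x - xa) / wa      ty = (y - ya) / ha
    tw = log(w / wa)        th = log(h / ha)

and the RPN objective is the two-term Faster-R-CNN-style cost

    L = (1/Ncls) sum_i Lcls(pi, pi*) + lambda (1/Nreg) sum_i pi* Lreg(ti, ti*)

with binary log loss for classification and smooth-L1 for regression;
only positive anchors (pi* = 1) contribute to the regression sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "Box", "BoxDelta", "AnchorAssignment", "RpnLossTerms",
    "generate_anchors", "encode_box", "decode_box", "smooth_l1",
    "box_iou_matrix", "assign_anchors", "sample_anchors", "rpn_loss",
    "select_proposals", "write_proposals", "read_proposals",
]

# exp() clamp for wild regression outputs, ln(1000/16)
_DELTA_CLAMP = float(np.log(1000.0 / 16.0))


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(f"degenerate box {self}")

    @property
    def w(self) -> float:
        return self.x2 - self.x1

    @property
    def h(self) -> float:
        return self.y2 - self.y1

    @property
    def x(self) -> float:
        return 0.5 * (self.x1 + self.x2)

    @property
    def y(self) -> float:
        return 0.5 * (self.y1 + self.y2)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass(frozen=True)
class BoxDelta:
    tx: float
    ty: float
    tw: float
    th: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tw, self.th], dtype=np.float64)


def _boxes_array(boxes) -> np.ndarray:
    if isinstance(boxes, Box):
        return boxes.as_array()[None, :]
    arr = np.asarray(boxes, dtype=np.float64)
    return arr[None, :] if arr.ndim == 1 else arr


def _centers(arr: np.ndarray):
    w = arr[:, 2] - arr[:, 0]
    h = arr[:, 3] - arr[:, 1]
    x = arr[:, 0] + 0.5 * w
    y = arr[:, 1] + 0.5 * h
    return x, y, w, h


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def generate_anchors(scales, ratios, locations, stride: int,
                     base_size: float = 16.0) -> np.ndarray:
    """Tile |scales| x |ratios| anchors over feature-grid locations.

    ``locations`` is either a ``(rows, cols)`` grid shape (all positions)
    or an iterable of ``(row, col)`` positions.  Each location maps to
    the image point ``((col + 0.5) * stride, (row + 0.5) * stride)``.
    At fixed scale the anchor area is invariant under the aspect ratio:
    ``w = base * scale / sqrt(ratio)``, ``h = base * scale * sqrt(ratio)``.
    """
    scales = np.asarray(scales, dtype=np.float64)
    ratios = np.asarray(ratios, dtype=np.float64)
    if scales.size == 0 or ratios.size == 0:
        raise ValueError("scales and ratios must be non-empty")
    if (scales <= 0).any() or (ratios <= 0).any():
        raise ValueError("scales and ratios must be positive")
    if isinstance(locations, tuple) and len(locations) == 2 and \
            all(isinstance(v, (int, np.integer)) for v in locations):
        rows, cols = locations
        locs = [(r, c) for r in range(rows) for c in range(cols)]
    else:
        locs = [tuple(rc) for rc in locations]
    ws = (base_size * scales[:, None] / np.sqrt(ratios)[None, :]).ravel()
    hs = (base_size * scales[:, None] * np.sqrt(ratios)[None, :]).ravel()
    anchors = np.empty((len(locs) * ws.size, 4), dtype=np.float64)
    k = 0
    for r, c in locs:
        cx = (c + 0.5) * stride
        cy = (r + 0.5) * stride
        for w, h in zip(ws, hs):
            anchors[k] = (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            k += 1
    return anchors


# ---------------------------------------------------------------------------
# box codec
# ---------------------------------------------------------------------------

def encode_box(box, anchor):
    """Parameterize ``box`` against ``anchor`` as (tx, ty, tw, th)."""
    b, a = _boxes_array(box), _boxes_array(anchor)
    ax, ay, aw, ah = _centers(a)
    if (aw <= 0).any() or (ah <= 0).any():
        raise ValueError("degenerate anchor (non-positive width or height)")
    bx, by, bw, bh = _centers(b)
    deltas = np.stack([(bx - ax) / aw, (by - ay) / ah,
                       np.log(bw / aw), np.log(bh / ah)], axis=1)
    if isinstance(box, Box) or np.asarray(box).ndim == 1:
        return BoxDelta(*deltas[0])
    return deltas


def decode_box(delta, anchor, clip_to=None, warn_on_clamp: bool = True):
    """Invert :func:`encode_box`.  ``clip_to=(H, W)`` clips to image bounds.

    Log-size components beyond ln(1000/16) are clamped (with a warning,
    unless suppressed) before exponentiation so wild predictions cannot
    overflow.
    """
    single = isinstance(delta, BoxDelta) or np.asarray(
        delta.as_array() if isinstance(delta, BoxDelta) else delta).ndim == 1
    d = delta.as_array()[None, :] if isinstance(delta, BoxDelta) else \
        np.atleast_2d(np.asarray(delta, dtype=np.float64))
    a = _boxes_array(anchor)
    ax, ay, aw, ah = _centers(a)
    tw, th = d[:, 2], d[:, 3]
    if (np.abs(tw) > _DELTA_CLAMP).any() or (np.abs(th) > _DELTA_CLAMP).any():
        if warn_on_clamp:
            warnings.warn("box delta log-size clamped to +/- ln(1000/16)",
                          RuntimeWarning)
        tw = np.clip(tw, -_DELTA_CLAMP, _DELTA_CLAMP)
        th = np.clip(th, -_DELTA_CLAMP, _DELTA_CLAMP)
    x = d[:, 0] * aw + ax
    y = d[:, 1] * ah + ay
    w = np.exp(tw) * aw
    h = np.exp(th) * ah
    boxes = np.stack([x - w / 2, y - h / 2, x + w / 2, y + h / 2], axis=1)
    if clip_to is not None:
        H, W = clip_to
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, W)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, H)
    if single:
        return Box(*boxes[0])
    return boxes


def smooth_l1(x):
    """Elementwise smooth-L1: 0.5 x^2 for |x| <= 1, |x| - 0.5 otherwise."""
    x = np.asarray(x, dtype=np.float64)
    absx = np.abs(x)
    out = np.where(absx <= 1.0, 0.5 * x * x, absx - 0.5)
    return float(out) if out.ndim == 0 else out


def _smooth_l1_t(x: Tensor) -> Tensor:
    """Differentiable smooth-L1 on a tensor (same piecewise form)."""
    quad_mask = (np.abs(x.data) <= 1.0).astype(np.float64)
    quad = x * x * 0.5
    lin = x.abs() - 0.5
    return quad * quad_mask + lin * (1.0 - quad_mask)


# ---------------------------------------------------------------------------
# assignment and loss
# ---------------------------------------------------------------------------

def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two half-open box arrays, (len(a), len(b))."""
    a, b = _boxes_array(a), _boxes_array(b)
    ix = np.maximum(0.0, np.minimum(a[:, None, 2], b[None, :, 2]) -
                    np.maximum(a[:, None, 0], b[None, :, 0]))
    iy = np.maximum(0.0, np.minimum(a[:, None, 3], b[None, :, 3]) -
                    np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)


@dataclass
class AnchorAssignment:
    """Per-anchor label: +1 positive, 0 negative, -1 ignore."""

    labels: np.ndarray
    matched_gt: np.ndarray       # gt index for positives, -1 elsewhere
    max_iou: np.ndarray

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


def assign_anchors(anchors: np.ndarray, gt_boxes: np.ndarray,
                   iou_hi: float = 0.7, iou_lo: float = 0.3) -> AnchorAssignment:
    """Label anchors positive/negative/ignore against ground-truth boxes.

    Positive: IoU >= ``iou_hi``, or the anchor is (one of) the best for
    some ground-truth box (the argmax rescue, so every overlapped box
    gets at least one positive anchor).  Negative: max IoU < ``iou_lo``.
    Anything between is ignored.
    """
    if iou_lo > iou_hi:
        raise ValueError("iou_lo must be <= iou_hi")
    anchors = _boxes_array(anchors)
    n = len(anchors)
    if len(gt_boxes) == 0:
        return AnchorAssignment(np.zeros(n, dtype=np.int8),
                                np.full(n, -1, dtype=np.int64),
                                np.zeros(n))
    iou = box_iou_matrix(anchors, gt_boxes)
    max_iou = iou.max(axis=1)
    matched = iou.argmax(axis=1)
    labels = np.full(n, -1, dtype=np.int8)
    labels[max_iou < iou_lo] = 0
    labels[max_iou >= iou_hi] = 1
    best_per_gt = iou.max(axis=0)
    for g in range(iou.shape[1]):
        if best_per_gt[g] > 0:
            rescued = np.flatnonzero(iou[:, g] == best_per_gt[g])
            labels[rescued] = 1
            matched[rescued] = g
    matched_gt = np.where(labels == 1, matched, -1)
    return AnchorAssignment(labels, matched_gt, max_iou)


def sample_anchors(assignment: AnchorAssignment, rng,
                   batch_size: int = 256, positive_fraction: float = 0.5) -> np.ndarray:
    """Subsample anchors for one loss evaluation (1:1 pos:neg up to budget).

    Returns indices of the kept anchors.
    """
    pos = assignment.positive_indices
    neg = assignment.negative_indices
    n_pos = min(len(pos), int(batch_size * positive_fraction))
    if len(pos) > n_pos:
        pos = rng.choice(pos, size=n_pos, replace=False)
    n_neg = min(len(neg), batch_size - n_pos)
    if len(neg) > n_neg:
        neg = rng.choice(neg, size=n_neg, replace=False)
    return np.concatenate([np.sort(pos), np.sort(neg)])


@dataclass
class RpnLossTerms:
    total: Tensor
    cls_term: Tensor
    reg_term: Tensor
    n_cls: int
    n_reg: int
    lam: float


def rpn_loss(probs, deltas, assignment: AnchorAssignment, target_deltas,
             lam: float = 1.0, n_cls: int | None = None,
             n_reg: int | None = None) -> RpnLossTerms:
    """Two-term RPN cost; ignore-labeled anchors touch neither term.

    ``probs`` are per-anchor objectness probabilities in [0, 1] (clamped
    inside the log), ``deltas`` the predicted (tx, ty, tw, th) rows, and
    ``target_deltas`` the encoded ground-truth rows (used for positives
    only).  Accepts tensors (differentiable) or plain arrays.
    """
    probs = as_tensor(probs)
    deltas = as_tensor(deltas)
    target_deltas = np.asarray(
        target_deltas.data if isinstance(target_deltas, Tensor) else target_deltas,
        dtype=np.float64)
    labels = assignment.labels
    used = np.flatnonzero(labels >= 0)
    pos = np.flatnonzero(labels == 1)
    n_cls = n_cls if n_cls is not None else max(1, len(used))
    n_reg = n_reg if n_reg is not None else max(1, len(pos))

    p = probs[used].clip(1e-7, 1.0 - 1e-7)
    y = labels[used].astype(np.float64)
    cls_sum = -(as_tensor(y) * p.log() + as_tensor(1.0 - y) * (1.0 - p).log()).sum()
    cls_term = cls_sum * (1.0 / n_cls)

    if len(pos):
        diff = deltas[pos] - as_tensor(target_deltas[pos])
        reg_term = _smooth_l1_t(diff).sum() * (lam / n_reg)
    else:
        reg_term = as_tensor(0.0)
    return RpnLossTerms(total=cls_term + reg_term, cls_term=cls_term,
                        reg_term=reg_term, n_cls=n_cls, n_reg=n_reg, lam=lam)


# ---------------------------------------------------------------------------
# proposal selection
# ---------------------------------------------------------------------------

def select_proposals(boxes: np.ndarray, scores: np.ndarray,
                     pre_nms_top_k: int = 1000, nms_iou: float = 0.7,
                     post_nms_top_k: int = 300):
    """Descending-score truncation, greedy NMS, final truncation.

    Deterministic: score ties are broken by lower box index.  Returns
    ``(boxes, scores, kept_indices)`` referring to the input ordering.
    """
    boxes = _boxes_array(boxes)
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")[:pre_nms_top_k]
    kept = []
    suppressed = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if suppressed[i]:
            continue
        kept.append(order[i])
        if len(kept) >= post_nms_top_k:
            break
        rest = order[i + 1:]
        live = ~suppressed[i + 1:]
        if rest[live].size:
            ious = box_iou_matrix(boxes[order[i]][None, :], boxes[rest[live]])[0]
            idx = np.flatnonzero(live)[ious > nms_iou]
            suppressed[i + 1 + idx] = True
    kept = np.asarray(kept, dtype=np.int64)
    return boxes[kept], scores[kept], kept


def write_proposals(path, boxes: np.ndarray, scores: np.ndarray) -> None:
    """Plain-text export: one ``x1 y1 x2 y2 score`` line per proposal."""
    with open(path, "w") as fh:
        for (x1, y1, x2, y2), s in zip(_boxes_array(boxes), scores):
            fh.write(f"{x1:.4f} {y1:.4f} {x2:.4f} {y2:.4f} {s:.6f}\n")


def read_proposals(path):
    rows = np.loadtxt(path, ndmin=2)
    if rows.size == 0:
        return np.zeros((0, 4)), np.zeros(0)
    return rows[:, :4], rows[:, 4]
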