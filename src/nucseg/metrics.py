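"""Object- and pixel-level scoring for instance segmentation.

Object level: tight boxes from masks, greedy one-to-one IoU matching,
and F1 = 2TP / (2TP + FP + FN).  Pixel level: the Jaccard index
|A ∩ B| / |A ∪ B| and the Aggregated Jaccard Index (AJI): for every
ground-truth instance the best-Jaccard prediction is matched, its
intersection and union pixel counts accumulate into C and U, and every
prediction left unmatched afterwards adds its full pixel count to U;
the score is C / U.  A naive pixel-set oracle with no shared code
provides an independent cross-check for the fast implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rpn import Box
from .synthetic import as_label_map

__all__ = [
    "DetectionCounts", "MatchAccumulator", "mask_to_bbox", "jaccard",
    "match_instances", "f1_score", "aji", "aji_bruteforce_oracle",
]


@dataclass(frozen=True)
class DetectionCounts:
    """True/false positive and false negative instance counts."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MatchAccumulator:
    """Running AJI counters: intersection C, union U, used predictions."""

    C: int = 0
    U: int = 0
    used: set = None

    def __post_init__(self):
        if self.used is None:
            self.used = set()

    @property
    def score(self) -> float:
        return self.C / self.U if self.U else 0.0


def mask_to_bbox(mask: np.ndarray) -> Box:
    """Tight half-open box around a binary mask's foreground."""
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    return Box(float(xs.min()), float(ys.min()),
               float(xs.max() + 1), float(ys.max() + 1))


def jaccard(a, b) -> float:
    """Jaccard index of two pixel sets (boolean masks) or two boxes."""
    if isinstance(a, Box) or isinstance(b, Box):
        if not (isinstance(a, Box) and isinstance(b, Box)):
            raise TypeError("mixed box/mask arguments")
        ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
        iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
        inter = ix * iy
        union = a.w * a.h + b.w * b.h - inter
        return inter / union
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return int((a & b).sum()) / union


def _instance_masks(labels):
    labels = as_label_map(labels)
    return {i: labels.grid == i for i in labels.ids}


def match_instances(gt, pred, iou_threshold: float = 0.5):
    """Greedy one-to-one matching in descending IoU; returns counts + pairs.

    Pairs with IoU >= ``iou_threshold`` are true positives; unmatched
    predictions are false positives, unmatched ground truths false
    negatives.
    """
    gt, pred = as_label_map(gt), as_label_map(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"size mismatch {gt.shape} vs {pred.shape}")
    gt_masks = _instance_masks(gt)
    pred_masks = _instance_masks(pred)
    candidates = []
    for gi, gm in gt_masks.items():
        for pi, pm in pred_masks.items():
            inter = int((gm & pm).sum())
            if inter:
                iou = inter / int((gm | pm).sum())
                if iou >= iou_threshold:
                    candidates.append((iou, gi, pi))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_gt, used_pred, pairs = set(), set(), []
    for iou, gi, pi in candidates:
        if gi in used_gt or pi in used_pred:
            continue
        used_gt.add(gi)
        used_pred.add(pi)
        pairs.append((gi, pi, iou))
    tp = len(pairs)
    counts = DetectionCounts(TP=tp, FP=len(pred_masks) - tp, FN=len(gt_masks) - tp)
    return counts, pairs


def f1_score(counts: DetectionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN)."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        raise ValueError("F1 undefined when TP, FP and FN are all zero")
    return 2 * counts.TP / denom


def aji(gt, pred) -> float:
    """Aggregated Jaccard Index between two instance label maps.

    Each ground-truth instance greedily claims the prediction with the
    highest Jaccard overlap (argmax ties broken by lowest prediction
    id); claimed intersections/unions accumulate into C/U, and pixels
    of predictions never claimed are added to U.  Predictions may be
    claimed by more than one ground-truth instance, matching the
    published algorithm.
    """
    gt, pred = as_label_map(gt), as_label_map(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"size mismatch {gt.shape} vs {pred.shape}")
    gt_ids = gt.ids
    if not gt_ids:
        raise ValueError("AJI undefined without ground-truth instances")
    pred_ids = pred.ids
    if not pred_ids:
        return 0.0
    # pixel-count contingency table via joint histogram
    g = gt.grid.ravel()
    p = pred.grid.ravel()
    n_g, n_p = int(g.max()) + 1, int(p.max()) + 1
    joint = np.bincount(g.astype(np.int64) * n_p + p.astype(np.int64),
                        minlength=n_g * n_p).reshape(n_g, n_p)
    g_areas = joint.sum(axis=1)
    p_areas = joint.sum(axis=0)
    acc = MatchAccumulator()
    for gi in gt_ids:
        inter = joint[gi, :]
        union = g_areas[gi] + p_areas - inter
        scores = np.where(np.array([pi in pred_ids for pi in range(n_p)]),
                          inter / np.maximum(union, 1), -1.0)
        scores[0] = -1.0
        j = int(scores.argmax())          # argmax ties -> lowest prediction id
        acc.C += int(inter[j])
        acc.U += int(union[j])
        acc.used.add(j)
    for pi in pred_ids:
        if pi not in acc.used:
            acc.U += int(p_areas[pi])
    return acc.score


def aji_bruteforce_oracle(gt, pred) -> float:
    """AJI by naive exhaustive pixel-set operations (independent oracle).

    Same definition as :func:`aji`, computed with Python sets of pixel
    coordinates and no shared code; intended for small maps.
    """
    gt, pred = as_label_map(gt), as_label_map(pred)
    if gt.shape != pred.shape:
        raise ValueError("size mismatch")
    def pixel_sets(label_map):
        sets = {}
        for (r, c), v in np.ndenumerate(label_map.grid):
            if v != 0:
                sets.setdefault(int(v), set()).add((r, c))
        return sets
    gt_sets = pixel_sets(gt)
    pred_sets = pixel_sets(pred)
    if not gt_sets:
        raise ValueError("AJI undefined without ground-truth instances")
    if not pred_sets:
        return 0.0
    C = U = 0
    used = set()
    for gi in sorted(gt_sets):
        best_j, best_score = None, -1.0
        for pi in sorted(pred_sets):
            inter = len(gt_sets[gi] & pred_sets[pi])
            union = len(gt_sets[gi] | pred_sets[pi])
            score = inter / union
            if score > best_score:
                best_j, best_score = pi, score
        C += len(gt_sets[gi] & pred_sets[best_j])
        U += len(gt_sets[gi] | pred_sets[best_j])
        used.add(best_j)
    for pi in sorted(pred_sets):
        if pi not in used:
            U += len(pred_sets[pi])
    return C / U
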