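"""End-to-end orchestration: train, predict, evaluate, checkpoints.

The training loop follows the two-stage recipe: each iteration draws
one (optionally augmented) image, derives ground-truth boxes from the
instance masks, evaluates the region-proposal loss on a sampled anchor
batch and the head losses (softmax classification, box regression,
binary mask) on sampled regions of interest, sums them into the
multi-task objective, and applies a gradient-clipped AMSGrad update.
Published defaults: staged learning rates 1e-4 / 1e-5 / 1e-6 over up
to 20 / 40 / 75 epochs, gradient clip norm 5.0, batch size 1 with
group normalization.

Runs are deterministic given the seed: all randomness flows from one
generator, and checkpoints round-trip weights bitwise.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import rpn as R
from .augment import random_augment
from .backbone import BackboneConfig, StageSpec, tiny_config
from .heads import DetectionResult, detections_to_label_map, multi_task_loss
from .metrics import aji, f1_score, mask_to_bbox, match_instances
from .model import ModelConfig, NucleusMaskRCNN, tiny_model_config
from .nn import softmax_cross_entropy, sigmoid_bce_with_logits
from .norm import NormSpec
from .optim import AMSGrad
from .rpn import _smooth_l1_t
from .synthetic import (InstanceLabelMap, SyntheticScene, as_label_map,
                        read_instance_layout, write_instance_layout)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "ModelCheckpoint", "train", "predict", "evaluate",
    "save_checkpoint", "load_checkpoint", "build_model",
    "toy_train_config", "EvaluationReport",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (published defaults)."""

    learning_rates: tuple[float, ...] = (1e-4, 1e-5, 1e-6)
    stage_epochs: tuple[int, ...] = (20, 40, 75)
    optimizer: str = "amsgrad"
    grad_clip_norm: float = 5.0
    batch_size: int = 1
    normalization: str = "group"
    max_proposals_train: int = 512
    max_proposals_infer: int = 1000
    iterations: int = 1000
    rpn_batch: int = 256
    roi_batch: int = 32
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(lr <= 0 for lr in self.learning_rates):
            raise ValueError("learning rates must be positive")
        if any(a < b for a, b in zip(self.learning_rates, self.learning_rates[1:])):
            raise ValueError("learning rates must be non-increasing across stages")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_for_epoch(self, epoch: int) -> float:
        bound = 0
        for lr, span in zip(self.learning_rates, self.stage_epochs):
            bound += span
            if epoch < bound:
                return lr
        return self.learning_rates[-1]


def toy_train_config(**overrides) -> TrainConfig:
    """Desk-scale preset: 200 iterations, constant 1e-3, no augmentation."""
    defaults = dict(learning_rates=(1e-3, 1e-3, 1e-3), iterations=200,
                    augment=False, rpn_batch=64, roi_batch=24, seed=0)
    defaults.update(overrides)
    return TrainConfig(**defaults)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass
class ModelCheckpoint:
    model_config: ModelConfig
    train_config: TrainConfig
    iteration: int
    weights: dict
    optimizer_state: dict | None = None


def _norm_from_dict(d) -> NormSpec:
    return NormSpec(**d)


def _backbone_from_dict(d) -> BackboneConfig:
    d = dict(d)
    d["stages"] = tuple(StageSpec(**s) for s in d["stages"])
    d["rates"] = tuple(d["rates"])
    d["normalization"] = _norm_from_dict(d["normalization"])
    return BackboneConfig(**d)


def _model_config_from_dict(d) -> ModelConfig:
    d = dict(d)
    d["backbone"] = _backbone_from_dict(d["backbone"])
    for key in ("rpn_levels", "anchor_scales", "anchor_ratios"):
        d[key] = tuple(d[key])
    return ModelConfig(**d)


def _train_config_from_dict(d) -> TrainConfig:
    d = dict(d)
    d["learning_rates"] = tuple(d["learning_rates"])
    d["stage_epochs"] = tuple(d["stage_epochs"])
    return TrainConfig(**d)


def save_checkpoint(ckpt: ModelCheckpoint, path) -> None:
    meta = json.dumps({
        "model_config": asdict(ckpt.model_config),
        "train_config": asdict(ckpt.train_config),
        "iteration": ckpt.iteration,
        "has_optimizer": ckpt.optimizer_state is not None,
    })
    arrays = {f"w/{k}": v for k, v in ckpt.weights.items()}
    if ckpt.optimizer_state:
        arrays.update({f"opt/{k}": v for k, v in ckpt.optimizer_state.items()})
    np.savez(Path(path), __meta__=np.array(meta), **arrays)


def load_checkpoint(path) -> ModelCheckpoint:
    with np.load(Path(path)) as data:
        meta = json.loads(str(data["__meta__"]))
        weights = {k[2:]: data[k].copy() for k in data.files if k.startswith("w/")}
        opt_state = {k[4:]: data[k].copy() for k in data.files if k.startswith("opt/")} \
            if meta["has_optimizer"] else None
    return ModelCheckpoint(
        model_config=_model_config_from_dict(meta["model_config"]),
        train_config=_train_config_from_dict(meta["train_config"]),
        iteration=meta["iteration"], weights=weights, optimizer_state=opt_state)


def build_model(ckpt: ModelCheckpoint) -> NucleusMaskRCNN:
    model = NucleusMaskRCNN(ckpt.model_config)
    model.load_state_dict(ckpt.weights)
    return model


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def _load_dataset(dataset) -> list[tuple[np.ndarray, InstanceLabelMap]]:
    if isinstance(dataset, (str, Path)):
        root = Path(dataset)
        pairs = []
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            import imageio.v3 as iio
            image = iio.imread(sub / "image.png")
            if image.ndim == 2:
                image = np.stack([image] * 3, axis=-1)
            pairs.append((image[..., :3], read_instance_layout(sub)))
        return pairs
    out = []
    for item in dataset:
        if isinstance(item, SyntheticScene):
            out.append((item.image, item.labels))
        else:
            image, labels = item
            out.append((image, as_label_map(labels)))
    return out


def _gt_boxes(labels: InstanceLabelMap) -> tuple[np.ndarray, list[int]]:
    boxes, ids = [], []
    for i in labels.ids:
        boxes.append(mask_to_bbox(labels.mask(i)).as_array())
        ids.append(i)
    return (np.stack(boxes) if boxes else np.zeros((0, 4))), ids


def _mask_target(labels: InstanceLabelMap, instance_id: int, box, size: int) -> np.ndarray:
    """Ground-truth instance mask cropped to a box and resized to size x size."""
    H, W = labels.shape
    x1, y1, x2, y2 = box
    xi1, yi1 = max(0, int(np.floor(x1))), max(0, int(np.floor(y1)))
    xi2, yi2 = min(W, int(np.ceil(x2))), min(H, int(np.ceil(y2)))
    crop = (labels.grid[yi1:yi2, xi1:xi2] == instance_id).astype(np.float64)
    if crop.size == 0:
        return np.zeros((size, size))
    return _sk_resize(crop, (size, size), order=0, mode="edge",
                      anti_aliasing=False)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sample_rois(gt_boxes, gt_ids, image_shape, rng, n_total: int):
    """Training ROIs: ground-truth boxes, jittered copies, and negatives."""
    H, W = image_shape
    rois, roi_labels, roi_gt = [], [], []
    for box, gid in zip(gt_boxes, gt_ids):
        rois.append(box)
        roi_labels.append(1)
        roi_gt.append(gid)
        w, h = box[2] - box[0], box[3] - box[1]
        jit = box + rng.normal(0, 0.1, 4) * np.array([w, h, w, h])
        jit[0::2] = np.clip(jit[0::2], 0, W)
        jit[1::2] = np.clip(jit[1::2], 0, H)
        if jit[2] - jit[0] > 2 and jit[3] - jit[1] > 2:
            rois.append(jit)
            roi_labels.append(1)
            roi_gt.append(gid)
    n_neg = max(2, min(n_total - len(rois), len(rois)))
    tries = 0
    while n_neg > 0 and tries < 50 * n_neg:
        tries += 1
        s = rng.uniform(6, 20)
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        cand = np.array([cx - s / 2, cy - s / 2, cx + s / 2, cy + s / 2])
        cand[0::2] = np.clip(cand[0::2], 0, W)
        cand[1::2] = np.clip(cand[1::2], 0, H)
        if cand[2] - cand[0] < 3 or cand[3] - cand[1] < 3:
            continue
        if len(gt_boxes) and R.box_iou_matrix(cand[None], gt_boxes).max() >= 0.3:
            continue
        rois.append(cand)
        roi_labels.append(0)
        roi_gt.append(-1)
        n_neg -= 1
    return (np.stack(rois), np.asarray(roi_labels, dtype=np.int64),
            np.asarray(roi_gt, dtype=np.int64))


def _train_step(model: NucleusMaskRCNN, opt: AMSGrad, image, labels,
                cfg: TrainConfig, rng) -> dict:
    from .autodiff import as_tensor
    H, W = labels.shape
    gt_boxes, gt_ids = _gt_boxes(labels)
    model.train()
    levels = model.extract_features(image)

    # region-proposal loss on a sampled anchor batch
    anchors, probs, deltas = model.rpn_outputs(levels)
    assignment = R.assign_anchors(anchors, gt_boxes)
    idx = R.sample_anchors(assignment, rng, batch_size=cfg.rpn_batch)
    sub = R.AnchorAssignment(assignment.labels[idx], assignment.matched_gt[idx],
                             assignment.max_iou[idx])
    targets = np.zeros((len(idx), 4))
    pos = np.flatnonzero(sub.labels == 1)
    if len(pos):
        targets[pos] = R.encode_box(gt_boxes[sub.matched_gt[pos]], anchors[idx][pos])
    rpn_terms = R.rpn_loss(probs[idx], deltas[idx], sub, targets)

    # head losses on sampled regions of interest
    cls_loss = box_loss = mask_loss = as_tensor(0.0)
    if len(gt_boxes):
        rois, roi_labels, roi_gt = _sample_rois(gt_boxes, gt_ids, (H, W), rng,
                                                cfg.roi_batch)
        pooled = model.pool(levels, rois, model.config.pooled_size)
        cls_logits, box_deltas = model.class_box_head(pooled)
        cls_loss = softmax_cross_entropy(cls_logits, roi_labels)
        pos_idx = np.flatnonzero(roi_labels == 1)
        if len(pos_idx):
            gt_index = {gid: k for k, gid in enumerate(gt_ids)}
            matched = np.stack([gt_boxes[gt_index[roi_gt[i]]] for i in pos_idx])
            box_targets = R.encode_box(matched, rois[pos_idx])
            pred = box_deltas[pos_idx, 1, :]
            box_loss = _smooth_l1_t(pred - as_tensor(box_targets)).sum() \
                * (1.0 / len(pos_idx))
            mask_pooled = model.pool(levels, rois[pos_idx],
                                     model.config.mask_pooled_size)
            mask_logits = model.mask_head(mask_pooled)[:, 1]
            mask_targets = np.stack([
                _mask_target(labels, roi_gt[i], rois[i], model.config.mask_size)
                for i in pos_idx])
            mask_loss = sigmoid_bce_with_logits(mask_logits, mask_targets)

    total = multi_task_loss(rpn_terms, cls_loss, box_loss, mask_loss)
    if not np.isfinite(total.data):
        raise RuntimeError(
            f"training diverged: non-finite loss "
            f"(rpn={float(rpn_terms.total.data):.4g}, cls={float(cls_loss.data):.4g}, "
            f"box={float(box_loss.data):.4g}, mask={float(mask_loss.data):.4g})")
    model.zero_grad()
    total.backward()
    opt.step()
    return {"total": float(total.data),
            "rpn_cls": float(rpn_terms.cls_term.data),
            "rpn_reg": float(rpn_terms.reg_term.data),
            "cls": float(cls_loss.data),
            "box": float(box_loss.data),
            "mask": float(mask_loss.data)}


def train(config: TrainConfig, dataset, model_config: ModelConfig | None = None,
          resume_from: ModelCheckpoint | str | Path | None = None,
          out_dir=None):
    """Train a model; returns ``(ModelCheckpoint, loss_trace)``.

    ``dataset`` is a list of ``(image, labels)`` pairs, synthetic
    scenes, or a directory of instance layouts.  Deterministic given
    ``config.seed`` (single-threaded).
    """
    pairs = _load_dataset(dataset)
    if not pairs:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    start_iter = 0
    if resume_from is not None:
        ckpt = resume_from if isinstance(resume_from, ModelCheckpoint) \
            else load_checkpoint(resume_from)
        model_config = ckpt.model_config
        model = build_model(ckpt)
        opt = AMSGrad(model.parameters(), lr=config.lr_for_epoch(0),
                      clip_norm=config.grad_clip_norm)
        if ckpt.optimizer_state:
            opt.load_state_dict(ckpt.optimizer_state)
        start_iter = ckpt.iteration
        # fast-forward the data/augmentation stream to the saved iteration
        for _ in range(start_iter):
            rng.integers(0, 2 ** 31 - 1)
    else:
        if model_config is None:
            norm = NormSpec(kind=config.normalization, num_groups=8)
            model_config = tiny_model_config(backbone=tiny_config(norm))
        model = NucleusMaskRCNN(model_config,
                                rng=np.random.default_rng(config.seed + 1))
        opt = AMSGrad(model.parameters(), lr=config.lr_for_epoch(0),
                      clip_norm=config.grad_clip_norm)

    trace = []
    t0 = time.time()
    log_lines = []
    for it in range(start_iter, start_iter + config.iterations):
        step_seed = int(rng.integers(0, 2 ** 31 - 1))
        step_rng = np.random.default_rng(step_seed)
        image, labels = pairs[it % len(pairs)]
        if config.augment:
            image, labels, _ = random_augment(image, labels,
                                              seed=int(step_rng.integers(0, 2 ** 31 - 1)))
        epoch = it // len(pairs)
        opt.lr = config.lr_for_epoch(epoch)
        terms = _train_step(model, opt, image, labels, config, step_rng)
        terms["iteration"] = it
        trace.append(terms)
        if (it + 1) % 25 == 0 or it == start_iter:
            line = (f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] iter {it + 1} "
                    f"loss {terms['total']:.4f} (rpn {terms['rpn_cls']:.3f}/"
                    f"{terms['rpn_reg']:.3f} cls {terms['cls']:.3f} "
                    f"box {terms['box']:.3f} mask {terms['mask']:.3f})")
            logger.info(line)
            log_lines.append(line)

    ckpt = ModelCheckpoint(model_config=model_config, train_config=config,
                           iteration=start_iter + config.iterations,
                           weights=model.state_dict(),
                           optimizer_state=opt.state_dict())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(ckpt, out_dir / "checkpoint.npz")
        keys = ["iteration", "total", "rpn_cls", "rpn_reg", "cls", "box", "mask"]
        with open(out_dir / "loss_trace.tsv", "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in trace:
                fh.write("\t".join(str(row[k]) for k in keys) + "\n")
        (out_dir / "train_log.txt").write_text(
            "\n".join(log_lines) + f"\nfinished in {time.time() - t0:.1f}s\n")
    return ckpt, trace


# ---------------------------------------------------------------------------
# inference and scoring
# ---------------------------------------------------------------------------

def predict(model_or_ckpt, images, auto_pad: bool = False) -> list[list[DetectionResult]]:
    """Run inference on a list of images (uint8 H x W x 3 or grayscale)."""
    if isinstance(model_or_ckpt, (str, Path)):
        model_or_ckpt = load_checkpoint(model_or_ckpt)
    model = build_model(model_or_ckpt) if isinstance(model_or_ckpt, ModelCheckpoint) \
        else model_or_ckpt
    stride = model.total_stride
    out = []
    for image in images:
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        H, W = image.shape[:2]
        if H % stride or W % stride or H < 2 * stride or W < 2 * stride:
            if not auto_pad:
                raise ValueError(
                    f"image size {H}x{W} must be a multiple of the total "
                    f"stride {stride} (and at least {2 * stride}); "
                    f"pass auto_pad=True to pad")
            Hp = max(2 * stride, int(np.ceil(H / stride)) * stride)
            Wp = max(2 * stride, int(np.ceil(W / stride)) * stride)
            padded = np.zeros((Hp, Wp, 3), dtype=image.dtype)
            padded[:H, :W] = image
            results = model.detect(padded)
            clipped = []
            for r in results:
                mask = r.mask[:H, :W]
                if mask.any():
                    clipped.append(DetectionResult(r.class_id, r.score,
                                                   np.clip(r.box, 0, [W, H, W, H]),
                                                   mask))
            out.append(clipped)
        else:
            out.append(model.detect(image))
    return out


@dataclass
class EvaluationReport:
    per_image: list[dict] = field(default_factory=list)
    mean_f1: float = 0.0
    mean_aji: float = 0.0

    def to_tsv(self) -> str:
        lines = ["image\tf1\taji"]
        for row in self.per_image:
            lines.append(f"{row['image']}\t{row['f1']:.6f}\t{row['aji']:.6f}")
        lines.append(f"mean\t{self.mean_f1:.6f}\t{self.mean_aji:.6f}")
        return "\n".join(lines) + "\n"


def evaluate(pred, gt, iou_threshold: float = 0.5) -> EvaluationReport:
    """Score predictions against ground truth: per-image and mean F1/AJI.

    ``pred`` and ``gt`` are dicts name -> label map, lists of label
    maps, or directories of instance layouts (matched by subdirectory
    name; a mismatch raises with the missing names listed).
    """
    def to_map(obj):
        if isinstance(obj, (str, Path)):
            root = Path(obj)
            return {p.name: read_instance_layout(p)
                    for p in sorted(root.iterdir()) if p.is_dir()}
        if isinstance(obj, dict):
            return {k: as_label_map(v) for k, v in obj.items()}
        return {str(i): as_label_map(v) for i, v in enumerate(obj)}

    pred_maps, gt_maps = to_map(pred), to_map(gt)
    missing = sorted(set(gt_maps) ^ set(pred_maps))
    if missing:
        raise ValueError(f"image inventories differ; unmatched: {missing}")
    report = EvaluationReport()
    f1s, ajis = [], []
    for name in sorted(gt_maps):
        g, p = gt_maps[name], pred_maps[name]
        counts, _ = match_instances(g, p, iou_threshold)
        f1 = f1_score(counts) if (counts.TP + counts.FP + counts.FN) else 1.0
        score = aji(g, p) if g.ids else (1.0 if not p.ids else 0.0)
        f1s.append(f1)
        ajis.append(score)
        report.per_image.append({"image": name, "f1": f1, "aji": score})
    report.mean_f1 = float(np.mean(f1s)) if f1s else 0.0
    report.mean_aji = float(np.mean(ajis)) if ajis else 0.0
    return report


def predictions_to_layouts(results_per_image, images, out_root,
                           overwrite: bool = False) -> None:
    """Write per-image detections as instance layouts under ``out_root``."""
    out_root = Path(out_root)
    for i, (results, image) in enumerate(zip(results_per_image, images)):
        labels = detections_to_label_map(results, image.shape[:2])
        write_instance_layout((image, labels), out_root / f"image_{i:04d}",
                              overwrite=overwrite)
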