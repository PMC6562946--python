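"""The assembled dense-small-object instance segmentation network.

Backbone (multi-path dilated residual net) -> feature pyramid -> region
proposal head -> ROI-Align -> three branches (softmax classification,
box regression, mask FCN).  Anchors are distributed across pyramid
levels, each level's anchor area scaled to its stride; on presets where
dilation keeps several levels at one stride the levels share an anchor
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import rpn as R
from .autodiff import Tensor, concat
from .backbone import BackboneConfig, DilatedBackbone, tiny_config
from .fpn import FeaturePyramid
from .heads import (ClassBoxHead, DetectionResult, MaskHead, paste_mask,
                    roi_align)
from .nn import Conv2d, Module

__all__ = ["ModelConfig", "NucleusMaskRCNN", "tiny_model_config"]


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig
    pyramid_channels: int = 64
    rpn_levels: tuple[str, ...] = ("P2",)
    anchor_scales: tuple[float, ...] = (1.0, 1.5, 2.0)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    anchor_base: float = 8.0          # at the finest used level; scales with stride
    num_classes: int = 2              # nucleus vs background
    pooled_size: int = 7
    mask_pooled_size: int = 14
    mask_size: int = 28
    head_hidden: int = 128
    rpn_nms_iou: float = 0.7
    detection_nms_iou: float = 0.3
    score_threshold: float = 0.5
    mask_threshold: float = 0.5
    pre_nms_top_k: int = 512
    post_nms_top_k: int = 100


def tiny_model_config(**overrides) -> ModelConfig:
    """Desk-scale preset: tiny backbone, one pyramid level, small heads."""
    defaults = dict(backbone=tiny_config(), pyramid_channels=32,
                    rpn_levels=("P2",), anchor_base=8.0, head_hidden=64,
                    pre_nms_top_k=256, post_nms_top_k=50)
    defaults.update(overrides)
    return ModelConfig(**defaults)


class RpnHead(Module):
    """Shared 3x3 conv + 1x1 objectness/delta predictors per location."""

    def __init__(self, channels: int, anchors_per_loc: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv = Conv2d(channels, channels, 3, rng=rng)
        self.cls = Conv2d(channels, anchors_per_loc, 1, rng=rng, init_scale=0.1)
        self.box = Conv2d(channels, 4 * anchors_per_loc, 1, rng=rng, init_scale=0.1)
        self.anchors_per_loc = anchors_per_loc

    def __call__(self, level: Tensor):
        h = self.conv(level).relu()
        return self.cls(h), self.box(h)


class NucleusMaskRCNN(Module):
    """Two-stage instance segmentation model over synthetic or real scenes."""

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.backbone = DilatedBackbone(config.backbone, rng=rng)
        self.fpn = FeaturePyramid(config.backbone.stage_channels,
                                  config.pyramid_channels, rng=rng)
        A = len(config.anchor_scales) * len(config.anchor_ratios)
        self.rpn_head = RpnHead(config.pyramid_channels, A, rng=rng)
        self.class_box_head = ClassBoxHead(config.pyramid_channels,
                                           config.pooled_size,
                                           config.head_hidden,
                                           config.num_classes, rng=rng)
        self.mask_head = MaskHead(config.pyramid_channels, 32,
                                  config.num_classes, rng=rng)

    # -- geometry ------------------------------------------------------

    @property
    def total_stride(self) -> int:
        return self.config.backbone.total_stride

    def level_stride(self, level: str) -> int:
        return self.config.backbone.stage_strides["stage" + level.removeprefix("P")]

    def _min_used_stride(self) -> int:
        return min(self.level_stride(lv) for lv in self.config.rpn_levels)

    def anchors_for_level(self, level: str, grid_shape) -> np.ndarray:
        stride = self.level_stride(level)
        base = self.config.anchor_base * stride / self._min_used_stride()
        return R.generate_anchors(self.config.anchor_scales,
                                  self.config.anchor_ratios,
                                  grid_shape, stride, base_size=base)

    # -- forward pieces ------------------------------------------------

    def extract_features(self, image: np.ndarray):
        """uint8 H x W x 3 image -> pyramid levels (dict of tensors)."""
        x = image.astype(np.float64) / 255.0 - 0.5
        t = Tensor(x.transpose(2, 0, 1)[None])
        return self.fpn(self.backbone(t))

    def rpn_outputs(self, levels):
        """Flatten RPN predictions over the configured levels.

        Returns (anchors, objectness-prob tensor, delta tensor); ordering
        is level-major, then location row-major, then (scale, ratio).
        """
        A = self.rpn_head.anchors_per_loc
        anchor_parts, prob_parts, delta_parts = [], [], []
        for name in self.config.rpn_levels:
            level = levels[name]
            logits, deltas = self.rpn_head(level)
            h, w = level.shape[2:]
            anchor_parts.append(self.anchors_for_level(name, (h, w)))
            prob_parts.append(
                logits.reshape(A, h, w).transpose(1, 2, 0).reshape(-1).sigmoid())
            delta_parts.append(
                deltas.reshape(A, 4, h, w).transpose(2, 3, 0, 1).reshape(-1, 4))
        anchors = np.concatenate(anchor_parts, axis=0)
        probs = concat(prob_parts, axis=0) if len(prob_parts) > 1 else prob_parts[0]
        deltas = concat(delta_parts, axis=0) if len(delta_parts) > 1 else delta_parts[0]
        return anchors, probs, deltas

    def propose(self, levels, image_shape, pre_k=None, post_k=None):
        """Decode, clip and NMS-select proposals from the RPN outputs."""
        cfg = self.config
        anchors, probs, deltas = self.rpn_outputs(levels)
        boxes = R.decode_box(deltas.data, anchors, clip_to=image_shape,
                             warn_on_clamp=False)
        ok = (boxes[:, 2] - boxes[:, 0] > 1) & (boxes[:, 3] - boxes[:, 1] > 1)
        boxes, scores = boxes[ok], probs.data[ok]
        return R.select_proposals(boxes, scores,
                                  pre_nms_top_k=pre_k or cfg.pre_nms_top_k,
                                  nms_iou=cfg.rpn_nms_iou,
                                  post_nms_top_k=post_k or cfg.post_nms_top_k)

    def pool(self, levels, boxes, size: int):
        level = self.config.rpn_levels[0]
        scale = 1.0 / self.level_stride(level)
        return roi_align(levels[level][0], boxes, size, spatial_scale=scale)

    # -- inference -----------------------------------------------------

    def detect(self, image: np.ndarray) -> list[DetectionResult]:
        """Full inference on one image (deterministic)."""
        cfg = self.config
        H, W = image.shape[:2]
        self.eval()
        levels = self.extract_features(image)
        boxes, scores, _ = self.propose(levels, (H, W))
        if len(boxes) == 0:
            return []
        pooled = self.pool(levels, boxes, cfg.pooled_size)
        cls_logits, box_deltas = self.class_box_head(pooled)
        z = cls_logits.data - cls_logits.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        results: list[DetectionResult] = []
        for class_id in range(1, cfg.num_classes):
            keep = probs[:, class_id] >= cfg.score_threshold
            if not keep.any():
                continue
            refined = R.decode_box(box_deltas.data[keep, class_id, :],
                                   boxes[keep], clip_to=(H, W),
                                   warn_on_clamp=False)
            ok = (refined[:, 2] - refined[:, 0] > 1) & (refined[:, 3] - refined[:, 1] > 1)
            refined = refined[ok]
            cls_scores = probs[keep, class_id][ok]
            if len(refined) == 0:
                continue
            final_boxes, final_scores, _ = R.select_proposals(
                refined, cls_scores, pre_nms_top_k=len(refined),
                nms_iou=cfg.detection_nms_iou, post_nms_top_k=len(refined))
            mask_pooled = self.pool(levels, final_boxes, cfg.mask_pooled_size)
            mask_logits = self.mask_head(mask_pooled)
            mask_probs = 1.0 / (1.0 + np.exp(-mask_logits.data[:, class_id]))
            for b, s, mp in zip(final_boxes, final_scores, mask_probs):
                mask = paste_mask(mp, b, (H, W), cfg.mask_threshold)
                if mask.any():
                    results.append(DetectionResult(class_id=class_id,
                                                   score=float(s), box=b, mask=mask))
        return results

    # -- config (de)serialization ---------------------------------------

    def config_dict(self) -> dict:
        return asdict(self.config)
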