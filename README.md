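# nucseg

Instance segmentation of cell nuclei in microscopy images — the dense
small-object regime where images routinely hold 25–400 nuclei of 21 to
~1000 px each, touching and overlapping.  The package is aimed at
computational-pathology and image-analysis researchers who need a fully
inspectable, desk-scale implementation of a two-stage (Mask-R-CNN-style)
detector whose backbone is a **multi-path dilated residual network**,
plus the field's standard object- and pixel-level scores.

Everything runs on NumPy (the package ships its own compact
reverse-mode autodiff and layer stack), so the whole pipeline — from
synthetic data generation through training to scoring — is reproducible
bit-for-bit from a seed on one CPU.

## The model

* **Multi-path dilated residual block.**  A bottleneck residual block
  whose middle 3×3 stage runs parallel dilated convolutions with
  expansion rates (1, 2, 5), merged before the restoring 1×1
  convolution.  The rate-1 path plus the shortcut is exactly a plain
  bottleneck block; the extra paths enlarge the receptive field without
  shrinking the feature map.  Stacking a single even rate leaves input
  pixels that never reach the output (the gridding artifact) — the
  `backbone.coverage_map` analysis computes this exhaustively, and the
  multi-path block covers its union receptive field with no holes.
* **D-ResNet-16 / D-ResNet-64.**  Presets counting 16 and 64 weight
  layers (stem convolution + 3 per block, parallel paths counted once).
  Total output stride is 8; the two deepest stages replace striding
  with dilation 2 and 4, and channels are capped at 256.
* **DRN-FPN.**  Feature-pyramid fusion with lateral 1×1 connections and
  a top-down path; when consecutive stages share a spatial size (the
  dilated stages) the top-down step omits upsampling.
* **RPN.**  3 scales × 3 aspect ratios = 9 anchors per location, box
  parameterization t = ((x−xₐ)/wₐ, (y−yₐ)/hₐ, log w/wₐ, log h/hₐ), and
  the two-term cost
  L = (1/N_cls) Σᵢ L_cls(pᵢ, pᵢ*) + λ (1/N_reg) Σᵢ pᵢ* L_reg(tᵢ, tᵢ*)
  with binary log loss and smooth-L1 (0.5x² for |x| ≤ 1, |x| − 0.5
  otherwise); only positive anchors reach the regression sum.
* **Heads.**  ROI-Align (bilinear, no rounding) feeds a softmax
  classification branch (pᵢ = exp(θᵢᵀx)/Σₖ exp(θₖᵀx), with the cost,
  gradient, and SGD update also exposed as standalone functions), a box
  regression branch, and a small FCN mask branch.
* **Metrics.**  F1 = 2TP/(2TP+FP+FN) after greedy IoU matching;
  Jaccard |A∩B|/|A∪B|; and the Aggregated Jaccard Index
  AJI = C/U where each ground-truth instance accumulates its
  best-Jaccard prediction's intersection/union into C/U and every
  unmatched prediction adds its pixels to U.  `aji` is cross-checked
  exactly against a naive pixel-set oracle.
* **Normalization.**  Group or batch normalization, selectable; group
  statistics are per-sample, so training is stable at batch size 1.

A seeded synthetic generator (`nucseg.synthetic`) renders dense scenes
of boundary-jittered elliptical nuclei in two modes — brightfield
H&E-like (dark blue-purple nuclei on pink cytoplasm / grey-blue matrix)
and fluorescence (bright blobs on dark background) — with ground-truth
instance label maps and DSB2018-style per-instance mask layouts.

## Worked example

```python
import numpy as np
from nucseg import synthetic as S, pipeline as P
from nucseg.heads import detections_to_label_map

train = [S.generate_scene(s) for s in S.sample_scene_specs(32, seed=0)]
held  = [S.generate_scene(s) for s in S.sample_scene_specs(20, seed=1000)]

ckpt, trace = P.train(P.toy_train_config(iterations=200, seed=0), train)
print("loss:", round(trace[0]["total"], 3), "->", round(trace[-1]["total"], 3))

model = P.build_model(ckpt)
preds = [detections_to_label_map(model.detect(sc.image), sc.image.shape[:2])
         for sc in held]
report = P.evaluate(preds, [sc.labels for sc in held])
print("mean AJI:", round(report.mean_aji, 3), "mean F1:", round(report.mean_f1, 3))
```

Output (about 3 minutes on one CPU):

```
loss: 4.3 -> 0.283
mean AJI: 0.756 mean F1: 0.977
```

The multi-task loss falls from 4.3 to ~0.3 over 200 iterations at batch
size 1 with group normalization, and the model trained on 32 synthetic
fluorescence scenes recovers the 20 held-out scenes' instances with a
mean Aggregated Jaccard Index of 0.76 and detection F1 of 0.98 — i.e.
nearly every nucleus is found, with pixel-accurate masks on most.

The same flow is available from the shell:

```bash
nucseg synth --spec scene.yaml --out data
nucseg train --config train.yaml --data data --out run
nucseg predict --ckpt run/checkpoint.npz --images data --out pred
nucseg evaluate --pred pred --gt data --report report.tsv
```

## Layout

| module | contents |
| --- | --- |
| `nucseg.synthetic` | scene specs, generator, instance layouts, statistics |
| `nucseg.backbone` | multi-path blocks, D-ResNet presets, receptive-field/coverage analysis |
| `nucseg.fpn` | feature-pyramid fusion |
| `nucseg.rpn` | anchors, box codec, assignment, RPN loss, NMS |
| `nucseg.heads` | ROI-Align, softmax math, box/mask heads, multi-task loss |
| `nucseg.norm` | group/batch normalization |
| `nucseg.augment` | eight-transform stochastic augmentation with replayable records |
| `nucseg.metrics` | F1, Jaccard, AJI + brute-force oracle |
| `nucseg.model`, `nucseg.pipeline`, `nucseg.cli` | assembled detector, train/predict/evaluate, CLI |
| `nucseg.autodiff`, `nucseg.nn`, `nucseg.optim` | NumPy autodiff engine, layers, AMSGrad |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
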