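# Methods

## Problem setting

Nuclei in histopathology and fluorescence microscopy are a dense
small-object detection problem: tens to hundreds of instances per
image, areas from ~21 px upward, frequent adhesion and overlap.  Deep
backbones built for classification downsample aggressively, and small
objects vanish from the deep feature maps precisely where the semantic
information lives.  The design here balances receptive field against
feature resolution by replacing late-stage striding with dilated
convolutions inside residual blocks, and fusing the resulting stages
with a feature pyramid.

## The multi-path dilated residual block

Each block is a bottleneck: a 1×1 reduction, a middle 3×3 stage, a 1×1
restoration, and a shortcut.  The middle stage runs one 3×3 convolution
per expansion rate in parallel — default rates (1, 2, 5) — and merges
the paths (channel concatenation by default, summation as an option)
before the restoring 1×1.  Properties the tests pin down:

* With rates (1,) and sum merge the block is weight-for-weight a plain
  bottleneck residual block.
* A stride-1 dilated convolution with "same" padding of r·(k−1)/2
  preserves spatial size, so dilation never shrinks the grid.
* Stacking a single even rate (e.g. three rate-2 layers) leaves
  zero-contribution positions inside the receptive field — the gridding
  artifact, computed exhaustively by `coverage_map` via offset-chain
  enumeration (and cross-checked against the gradient influence map of
  a unit-weight convolution stack).  The multi-path block's merged
  coverage has no holes inside the union of its paths' fields.

Rates are configurable.  The default (1, 2, 5) keeps one path exactly
residual (rate 1), one odd and one even rate for complementary
coverage, and a large rate for context.

## Backbone presets and the layer-counting convention

Depth is counted as: one layer for the stem convolution, three per
block (1×1 reduce, the parallel dilated stage counted **once** — depth,
not width — and the 1×1 restore).  Projection shortcuts are not
counted.  Under this convention the classical (3, 4, 6, 3) bottleneck
layout counts 49 convolutions, and the presets are:

* **D-ResNet-64**: stem max-pool (stride 2) + 3×3 stride-2 convolution,
  then stages of (3, 4, 6, 8) blocks with output channels
  (64, 128, 256, 256) and bottleneck widths a quarter of that.  Total
  output stride 8 (stem 4 × stage-3 2); stages 4–5 keep stride 1 and
  multiply their path rates by base dilations 2 and 4.  1 + 3·21 = 64.
* **D-ResNet-16**: same stride/dilation plan with (1, 1, 1, 2) blocks;
  1 + 3·5 = 16.  Used for classification-scale verification of the
  block design.
* **tiny** (desk-scale): one block per stage, 32 channels, output
  stride 4.  Used by the toy recovery experiment and the test suite.

The stage partition of the 21 blocks is this package's choice; the
channel cap of 256 and the reduced downsampling are the design's fixed
points.

## Feature pyramid

Lateral 1×1 projections bring all stages to one width; the top-down
pass adds deeper levels into shallower ones, with nearest-neighbor 2×
upsampling only when the sizes differ by 2:1 — consecutive equal-size
(dilated) stages merge by direct addition, so the deepest stages of the
D-ResNet presets fuse without any upsampling.  A 3×3 convolution
smooths each output level.  Anchors are distributed across levels with
the anchor area scaled to the level's stride; each level keeps the full
3-scale × 3-ratio set per location.  On the tiny preset, where all
fused levels share one stride, the region heads read a single level.

## Region proposals and heads

Boxes are 0-based half-open; the codec is the standard center/log-size
parameterization, exactly invertible (round-trip < 1e-5 over random
pairs in the regression regime).  Decoded log-sizes are clamped to
±ln(1000/16) so wild predictions cannot overflow — the clamp is outside
the codec's exact-inversion domain by construction.

Anchor assignment: positive at IoU ≥ 0.7 or as a ground-truth box's
argmax anchor (ties all rescued), negative below 0.3, ignored between;
λ = 1, N_cls = sampled anchor count, N_reg = positive count (floor 1).
Up to 256 anchors per image are sampled at 1:1 positive:negative.
Ignored anchors provably touch neither loss term.  Proposal selection
is score-descending truncation, greedy NMS (ties broken by lower box
index, so runs are deterministic), and final truncation.

ROI-Align pools each proposal by bilinear sampling at 4 regularly
spaced points per bin (no coordinate rounding); it is linear in the
feature map and its exact adjoint is used in the backward pass.  The
classification branch is a softmax over k = 2 classes (nucleus vs
background); its hypothesis function, cost, analytic gradient, and SGD
update are exposed standalone and verified against finite differences.
The mask branch is a small FCN on a 14×14 pooled grid producing 28×28
per-class logits (the 2× upsampling is realized as nearest-neighbor
upsampling followed by a 3×3 convolution); its loss is mean binary
cross-entropy on the matched class's mask.  Head sizes (7×7 pooled,
hidden 128, mask 28×28) are conventional defaults, configurable.

The total objective is the unweighted sum of the RPN terms and the
three head terms (weights configurable).

## Normalization

Group normalization (32 groups by default, capped at the channel
count, ε = 1e-5) standardizes per sample and per group, making outputs
independent of batch composition — verified to < 1e-5 between batch
sizes 1 and 2.  Batch normalization with running statistics is provided
for comparison, including a frozen mode that always applies stored
statistics (the behaviour of pretrained, untrained batch norm).  The
detector defaults to group normalization because training runs at
batch size 1.

## Training procedure

Each iteration draws one image (augmented when enabled), derives
ground-truth boxes from the instance masks (never stored separately),
computes the RPN loss on a sampled anchor batch, and the head losses on
training ROIs: the ground-truth boxes, one jittered copy of each
(±10 % of the box size), and an equal number of random background
boxes with IoU < 0.3 against all ground truth.  Using ground-truth
boxes rather than live RPN proposals as head ROIs decouples the two
stages and makes desk-scale runs converge in a few hundred iterations;
at inference the heads consume genuine RPN proposals.

The optimizer is AMSGrad (the maximum-bound correction of the adaptive
moment update) with global gradient-norm clipping at 5.0.  Published
defaults: staged learning rates 1e-4 / 1e-5 / 1e-6 with stage lengths
20 / 40 / 75 epochs (read as a decay schedule; boundaries
configurable), batch size 1, group normalization.  The desk-scale
preset trains the tiny model from scratch and therefore uses a constant
1e-3 — a standard from-scratch Adam-family rate — with 200 iterations,
augmentation off, and 64 RPN / 24 ROI samples per step.

Training aborts with a diagnostic on a non-finite loss.  All
randomness flows from a single seeded generator, so two runs with one
seed produce identical loss traces; checkpoints store every weight and
optimizer moment as float64 and round-trip bitwise.

## Augmentation

Eight transforms: sharpening (unsharp mask), Gaussian noise, grayscale
conversion, contrast/brightness, random scaling (zoom about the center,
crop/pad back), rotation (multiples of 90°), flip, and channel
permutation.  One to three are drawn per call and superimposed in a
drawn order ("several" is not a fixed number; 1–3 is this package's
choice).  Geometric transforms hit the label map with nearest-neighbor
interpolation; photometric transforms never touch it.  Parameter ranges
are configurable defaults.  Every call returns a record that replays
bitwise; instances scaled to zero pixels are dropped with a logged
warning.

## Evaluation

* Object level: masks → tight boxes; greedy one-to-one matching in
  descending IoU at threshold 0.5 (configurable); F1 = 2TP/(2TP+FP+FN).
* Pixel level: Jaccard |A∩B|/|A∪B| and the Aggregated Jaccard Index.
  For AJI each ground-truth instance claims the prediction maximizing
  Jaccard (argmax ties broken by lowest prediction id; a prediction may
  be claimed more than once, matching the published algorithm);
  intersections and unions accumulate into C and U, unclaimed
  predictions add their full pixel count to U once, and the score is
  C/U.  The implementation is exactly cross-checked against an
  independent brute-force pixel-set oracle on seeded random maps.
  Predictions arriving as overlapping masks are first resolved into a
  partition by score order, since the metric assumes disjoint regions.

## The synthetic generator: what it emulates and what it does not

Scenes are boundary-jittered ellipses (radius jitter from two low
cosine harmonics, amplitude ≤ 0.08) with overlap resolved by placement
order, so the label map is always a partition; placement is rejected
when overlap exceeds the configured fraction or any instance would fall
below the minimum area, and an explicit error names the achieved count
when packing fails.  Defaults target the published dense regime: 40
nuclei per 256×256 scene, minimum instance area 21 px, dense meaning
more than 25 per image.  Brightfield scenes use a fixed H&E-like
palette (dark blue-purple nuclei ≈ (72, 58, 128), pink cytoplasm,
grey-blue matrix patches) with per-nucleus jitter; fluorescence scenes
are bright radial-falloff blobs on a dark background with additive
Gaussian noise.

Not emulated: chromatin texture, stain variation and bleed-through,
out-of-focus blur, true transparency of overlapping nuclei, imaging
artifacts.  Passing the desk-scale recovery test therefore shows the
pipeline is implemented coherently end to end (losses optimize the
right quantities, geometry round-trips, metrics reward the right
outputs); it does not certify accuracy on real stained tissue.

## The desk-scale recovery experiment

Tiny preset trained 200 iterations on 32 fluorescence scenes (64×64,
5–10 well-separated nuclei of radius 4–7 px, seed 0), evaluated on 20
held-out scenes.  The loss trace falls from ≈ 4.3 to ≈ 0.3 with a
monotone quarter-over-quarter trend, and held-out mean AJI is ≈ 0.76
(F1 ≈ 0.98), against an acceptance floor of 0.5.  Problem sizes were
chosen so the full experiment runs in about three minutes on one CPU.

## Numerical choices

* float64 throughout; probabilities clamped to [1e-7, 1−1e-7] inside
  logs; softmax computed with max subtraction.
* Max-pool gradients split equally among tied maxima; NMS and AJI ties
  broken by lowest index/id — all deterministic.
* Images smaller than (or not divisible by) the backbone stride raise
  an explicit size error, with an opt-in zero-padding fallback that
  crops masks back to the original frame.

## Known limitations

* CPU-only and desk-scale by design; the NumPy engine is exact but not
  fast, and no GPU path exists.
* The trainer optimizes head losses on ground-truth-derived ROIs, not
  on live proposals; large-scale training would normally switch to
  sampled proposals after warm-up.
* Instance crowding beyond the partition assumption (true transparent
  overlap) is out of scope, as are stain deconvolution and 3-D stacks.
* The 64/16 layer counts depend on the documented counting convention;
  other conventions would name the same architectures differently.
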