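"""Multi-path dilated residual backbones (D-ResNet-16 / D-ResNet-64).

The building block is a bottleneck residual block whose middle 3x3
stage runs several dilated convolutions in parallel (default expansion
rates 1, 2 and 5) and merges them before the restoring 1x1 convolution.
The rate-1 path plus the shortcut is exactly an ordinary bottleneck
residual block; the extra paths widen the receptive field without
shrinking the grid.

Late stages replace striding with dilation, so deep features keep the
spatial resolution small objects need.  The module also provides
receptive-field and pixel-coverage analysis for dilated stacks: a
closed-form extent, and an exhaustive offset-chain enumeration that
exposes the gridding artifact of same-rate stacking (positions inside
the receptive field that never contribute).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, Module, max_pool2d
from .norm import NormSpec, make_norm

__all__ = [
    "DilatedConvSpec", "MultiPathBlockSpec", "StageSpec", "BackboneConfig",
    "ConfigurationError", "MultiPathBlock", "DilatedBackbone",
    "build_block", "build_backbone", "count_weight_layers",
    "receptive_field", "coverage_map", "multipath_coverage_map",
    "dresnet64_config", "dresnet16_config", "tiny_config",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DilatedConvSpec:
    """One dilated convolution layer: odd kernel, expansion rate, stride."""

    kernel: int = 3
    rate: int = 1
    stride: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be a positive odd integer")
        if self.rate < 1:
            raise ValueError("expansion rate must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class MultiPathBlockSpec:
    """Declarative description of one multi-path dilated residual block."""

    in_channels: int
    bottleneck_channels: int
    out_channels: int
    rates: tuple[int, ...] = (1, 2, 5)
    merge: str = "concat"
    normalization: NormSpec = field(default_factory=NormSpec)
    stride: int = 1
    base_dilation: int = 1      # multiplies every path rate (dilation in lieu of stride)
    shortcut: str = "auto"      # auto | identity | projection

    def __post_init__(self):
        if not self.rates:
            raise ValueError("rates must be non-empty")
        if 1 not in self.rates:
            raise ValueError("rate list must contain 1 (plain-residual path)")
        if self.merge not in ("concat", "sum"):
            raise ValueError(f"unknown merge rule {self.merge!r}")
        needs_projection = self.out_channels != self.in_channels or self.stride != 1
        if self.shortcut == "identity" and needs_projection:
            raise ConfigurationError(
                "identity shortcut requires out_channels == in_channels and stride 1; "
                "use a projection shortcut")


class MultiPathBlock(Module):
    """1x1 reduce -> parallel dilated 3x3 paths -> merge -> 1x1 restore + shortcut."""

    def __init__(self, spec: MultiPathBlockSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        norm = spec.normalization
        c_in, c_mid, c_out = spec.in_channels, spec.bottleneck_channels, spec.out_channels
        self.reduce = Conv2d(c_in, c_mid, 1, rng=rng, bias=False)
        self.reduce_norm = make_norm(c_mid, norm)
        self.paths = [Conv2d(c_mid, c_mid, 3, stride=spec.stride,
                             dilation=r * spec.base_dilation, rng=rng, bias=False)
                      for r in spec.rates]
        self.path_norms = [make_norm(c_mid, norm) for _ in spec.rates]
        merged = c_mid * len(spec.rates) if spec.merge == "concat" else c_mid
        self.restore = Conv2d(merged, c_out, 1, rng=rng, bias=False)
        self.restore_norm = make_norm(c_out, norm)
        needs_projection = c_out != c_in or spec.stride != 1
        use_projection = spec.shortcut == "projection" or (
            spec.shortcut == "auto" and needs_projection)
        if use_projection:
            self.proj = Conv2d(c_in, c_out, 1, stride=spec.stride, rng=rng, bias=False)
            self.proj_norm = make_norm(c_out, norm)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.reduce_norm(self.reduce(x)).relu()
        branches = [pn(p(h)).relu() for p, pn in zip(self.paths, self.path_norms)]
        if self.spec.merge == "concat":
            merged = concat(branches, axis=1) if len(branches) > 1 else branches[0]
        else:
            merged = branches[0]
            for b in branches[1:]:
                merged = merged + b
        out = self.restore_norm(self.restore(merged))
        shortcut = self.proj_norm(self.proj(x)) if self.proj is not None else x
        return (out + shortcut).relu()


def build_block(spec: MultiPathBlockSpec, rng=None) -> MultiPathBlock:
    return MultiPathBlock(spec, rng=rng)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One stage: a run of blocks sharing channel widths and dilation."""

    blocks: int
    out_channels: int
    bottleneck_channels: int
    stride: int = 1      # applied by the first block
    dilation: int = 1    # base dilation for every block in the stage


@dataclass(frozen=True)
class BackboneConfig:
    stem_channels: int = 64
    stem_pool_stride: int = 2    # unweighted max pool; 1 disables pooling
    stem_conv_stride: int = 2    # 3x3 convolution stride
    stages: tuple[StageSpec, ...] = ()
    rates: tuple[int, ...] = (1, 2, 5)
    merge: str = "concat"
    normalization: NormSpec = field(default_factory=NormSpec)
    channel_cap: int = 256
    declared_depth: int | None = None

    def __post_init__(self):
        if not self.stages:
            return
        for s in self.stages:
            for c in (s.out_channels, s.bottleneck_channels):
                if c > self.channel_cap:
                    raise ConfigurationError(
                        f"stage channel count {c} exceeds cap {self.channel_cap}")
        if self.stem_channels > self.channel_cap:
            raise ConfigurationError("stem channels exceed cap")
        if self.declared_depth is not None:
            counted = count_weight_layers(self)
            if counted != self.declared_depth:
                raise ConfigurationError(
                    f"declared depth {self.declared_depth} != counted {counted}")

    @property
    def total_stride(self) -> int:
        s = self.stem_pool_stride * self.stem_conv_stride
        for st in self.stages:
            s *= st.stride
        return s

    @property
    def stage_names(self) -> list[str]:
        return [f"stage{i + 2}" for i in range(len(self.stages))]

    @property
    def stage_strides(self) -> dict[str, int]:
        out, s = {}, self.stem_pool_stride * self.stem_conv_stride
        for name, st in zip(self.stage_names, self.stages):
            s *= st.stride
            out[name] = s
        return out

    @property
    def stage_channels(self) -> dict[str, int]:
        return {name: st.out_channels
                for name, st in zip(self.stage_names, self.stages)}


def count_weight_layers(config: BackboneConfig) -> int:
    """Weight-layer count under the documented convention.

    One layer for the stem convolution (when a stem is configured), three
    per block (1x1 reduce, the parallel dilated stage counted once —
    depth, not width — and the 1x1 restore).  Projection shortcuts are
    not counted, matching the classical residual-network naming
    convention.
    """
    if not config.stages:
        return 0
    stem = 1 if config.stem_channels > 0 else 0
    return stem + 3 * sum(s.blocks for s in config.stages)


class DilatedBackbone(Module):
    """Stem plus stages of multi-path dilated residual blocks."""

    def __init__(self, config: BackboneConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if not config.stages:
            raise ConfigurationError("backbone needs at least one stage")
        if config.stem_channels < 1:
            raise ConfigurationError("a runnable backbone needs a stem")
        self.config = config
        in_ch = 3
        self.stem_conv = Conv2d(in_ch, config.stem_channels, 3,
                                stride=config.stem_conv_stride, rng=rng, bias=False)
        self.stem_norm = make_norm(config.stem_channels, config.normalization)
        self.stage_blocks: list[list[MultiPathBlock]] = []
        c_prev = config.stem_channels
        for st in config.stages:
            blocks = []
            for b in range(st.blocks):
                spec = MultiPathBlockSpec(
                    in_channels=c_prev if b == 0 else st.out_channels,
                    bottleneck_channels=st.bottleneck_channels,
                    out_channels=st.out_channels,
                    rates=config.rates, merge=config.merge,
                    normalization=config.normalization,
                    stride=st.stride if b == 0 else 1,
                    base_dilation=st.dilation)
                blocks.append(MultiPathBlock(spec, rng=rng))
            self.stage_blocks.append(blocks)
            c_prev = st.out_channels

    def __call__(self, x: Tensor) -> "OrderedDict[str, Tensor]":
        """Run the backbone; returns ordered stage-name -> feature map."""
        h = x
        if self.config.stem_pool_stride > 1:
            h = max_pool2d(h, self.config.stem_pool_stride)
        h = self.stem_norm(self.stem_conv(h)).relu()
        outputs = OrderedDict()
        for name, blocks in zip(self.config.stage_names, self.stage_blocks):
            for block in blocks:
                h = block(h)
            outputs[name] = h
        return outputs


def build_backbone(config: BackboneConfig, rng=None) -> DilatedBackbone:
    return DilatedBackbone(config, rng=rng)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def dresnet64_config(normalization: NormSpec | None = None) -> BackboneConfig:
    """64-weight-layer preset: stem conv + 21 blocks in stages (3, 4, 6, 8).

    Output stride 8 (stem 4, stage-3 2); the last two stages trade
    striding for dilation 2 and 4, and channels are capped at 256.
    """
    norm = normalization or NormSpec()
    return BackboneConfig(
        stem_channels=64, stem_pool_stride=2, stem_conv_stride=2,
        stages=(
            StageSpec(3, 64, 16, stride=1, dilation=1),
            StageSpec(4, 128, 32, stride=2, dilation=1),
            StageSpec(6, 256, 64, stride=1, dilation=2),
            StageSpec(8, 256, 64, stride=1, dilation=4),
        ),
        normalization=norm, declared_depth=64)


def dresnet16_config(normalization: NormSpec | None = None) -> BackboneConfig:
    """16-weight-layer preset (classification-scale verification network)."""
    norm = normalization or NormSpec()
    return BackboneConfig(
        stem_channels=64, stem_pool_stride=2, stem_conv_stride=2,
        stages=(
            StageSpec(1, 64, 16, stride=1, dilation=1),
            StageSpec(1, 128, 32, stride=2, dilation=1),
            StageSpec(1, 256, 64, stride=1, dilation=2),
            StageSpec(2, 256, 64, stride=1, dilation=4),
        ),
        normalization=norm, declared_depth=16)


def tiny_config(normalization: NormSpec | None = None) -> BackboneConfig:
    """Desk-scale preset: one block per stage, 32 channels, output stride 4."""
    norm = normalization or NormSpec(num_groups=8)
    return BackboneConfig(
        stem_channels=32, stem_pool_stride=1, stem_conv_stride=2,
        stages=(
            StageSpec(1, 32, 16, stride=2, dilation=1),
            StageSpec(1, 32, 16, stride=1, dilation=1),
            StageSpec(1, 32, 16, stride=1, dilation=2),
            StageSpec(1, 32, 16, stride=1, dilation=2),
        ),
        normalization=norm)


# ---------------------------------------------------------------------------
# receptive-field and coverage analysis
# ---------------------------------------------------------------------------

def receptive_field(stack: list[DilatedConvSpec]) -> int:
    """Closed-form receptive-field extent (pixels along one axis)."""
    if not stack:
        raise ValueError("stack must be non-empty")
    extent, jump = 1, 1
    for layer in stack:
        extent += (layer.kernel - 1) * layer.rate * jump
        jump *= layer.stride
    return extent


def _layer_offsets(spec: DilatedConvSpec) -> list[int]:
    half = (spec.kernel - 1) // 2
    return [spec.rate * (i - half) for i in range(spec.kernel)]


def coverage_map(stack: list[DilatedConvSpec], grid_size: int) -> np.ndarray:
    """Contribution counts of each input position to the center output.

    Exhaustive offset-chain enumeration over every combination of kernel
    taps through the stack (stride-1 stacks only).  Zero entries inside
    the receptive field are the gridding artifact.
    """
    if not stack:
        raise ValueError("stack must be non-empty")
    if any(s.stride != 1 for s in stack):
        raise ValueError("coverage analysis applies to stride-1 stacks")
    extent = receptive_field(stack)
    if grid_size < extent:
        raise ValueError(f"grid_size {grid_size} < receptive field extent {extent}")
    center = grid_size // 2
    counts = np.zeros((grid_size, grid_size), dtype=np.int64)
    axis_offsets = [_layer_offsets(s) for s in stack]
    for chain in product(*axis_offsets):
        dy = sum(chain)
        for chain_x in product(*axis_offsets):
            counts[center + dy, center + sum(chain_x)] += 1
    return counts


def multipath_coverage_map(rates: tuple[int, ...], kernel: int = 3,
                           grid_size: int | None = None,
                           include_shortcut: bool = True) -> np.ndarray:
    """Coverage counts for one multi-path block's parallel dilated stage.

    The parallel paths are merged by summation of their tap patterns;
    the identity shortcut contributes the center position.  Every
    position inside the union of the paths' receptive fields receives a
    nonzero count — the multi-path answer to the gridding artifact.
    """
    if not rates:
        raise ValueError("rates must be non-empty")
    extent = max(receptive_field([DilatedConvSpec(kernel=kernel, rate=r)])
                 for r in rates)
    grid_size = grid_size or extent
    if grid_size < extent:
        raise ValueError(f"grid_size {grid_size} < union extent {extent}")
    center = grid_size // 2
    counts = np.zeros((grid_size, grid_size), dtype=np.int64)
    for r in rates:
        offs = _layer_offsets(DilatedConvSpec(kernel=kernel, rate=r))
        for dy in offs:
            for dx in offs:
                counts[center + dy, center + dx] += 1
    if include_shortcut:
        counts[center, center] += 1
    return counts
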