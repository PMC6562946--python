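"""Feature-pyramid fusion over backbone stage outputs.

Lateral 1x1 projections bring every stage to a common channel width; a
top-down path accumulates deeper levels into shallower ones, followed by
a 3x3 smoothing convolution per level.  When two consecutive stages
share a spatial size — the dilated stages, where dilation replaced
striding — the top-down step adds them directly with no upsampling;
otherwise a nearest-neighbor 2x upsample precedes the addition.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor
from .nn import Conv2d, Module, upsample_nearest

__all__ = ["FeaturePyramid", "build_fpn"]


class FeaturePyramid(Module):
    """Fusion network; call :meth:`fuse` with backbone stage outputs."""

    def __init__(self, stage_channels: list[int] | dict, pyramid_channels: int = 256,
                 rng=None):
        super().__init__()
        if isinstance(stage_channels, dict):
            stage_channels = list(stage_channels.values())
        if len(stage_channels) < 2:
            raise ValueError("a pyramid needs at least two stages")
        rng = rng or np.random.default_rng(0)
        self.pyramid_channels = pyramid_channels
        self.laterals = [Conv2d(c, pyramid_channels, 1, rng=rng)
                         for c in stage_channels]
        self.smooths = [Conv2d(pyramid_channels, pyramid_channels, 3, rng=rng)
                        for _ in stage_channels]

    def fuse(self, stage_outputs: "OrderedDict[str, Tensor]") -> "OrderedDict[str, Tensor]":
        """Fuse ordered shallow-to-deep stage outputs into pyramid levels.

        Returns levels keyed ``P<i>`` aligned with the input stages
        (``stage2`` -> ``P2`` and so on), all at the common width.
        """
        names = list(stage_outputs)
        feats = list(stage_outputs.values())
        if len(feats) != len(self.laterals):
            raise ValueError(f"expected {len(self.laterals)} stages, got {len(feats)}")
        laterals = [lat(f) for lat, f in zip(self.laterals, feats)]
        merged = [None] * len(laterals)
        merged[-1] = laterals[-1]
        for i in range(len(laterals) - 2, -1, -1):
            upper, lower = merged[i + 1], laterals[i]
            uh, uw = upper.shape[2:]
            lh, lw = lower.shape[2:]
            if (uh, uw) == (lh, lw):
                merged[i] = lower + upper          # equal-resolution: no upsampling
            elif (2 * uh, 2 * uw) == (lh, lw):
                merged[i] = lower + upsample_nearest(upper, 2)
            else:
                raise ValueError(
                    f"stage sizes {lh}x{lw} vs {uh}x{uw} are neither equal nor 2:1")
        out = OrderedDict()
        for name, m, smooth in zip(names, merged, self.smooths):
            level = "P" + name.removeprefix("stage") if name.startswith("stage") else name
            out[level] = smooth(m)
        return out

    __call__ = fuse


def build_fpn(stage_channels, pyramid_channels: int = 256, rng=None) -> FeaturePyramid:
    return FeaturePyramid(stage_channels, pyramid_channels, rng=rng)
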