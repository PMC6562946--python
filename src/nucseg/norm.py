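"""Selectable feature normalization: group or batch statistics.

Group normalization standardizes each sample over channel groups, so
its output is independent of batch composition — the property that
keeps training stable at batch size 1, where batch normalization's
across-batch statistics collapse onto the single sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor
from .nn import Module

__all__ = ["NormSpec", "GroupNorm", "BatchNorm2d", "make_norm", "normalize"]


@dataclass(frozen=True)
class NormSpec:
    """Configuration for a normalization layer.

    kind
        ``"group"`` (per-sample channel-group statistics) or ``"batch"``
        (across-batch per-channel statistics with running averages).
    num_groups
        Group count for group normalization; channels must divide evenly.
        Capped at the channel count when the layer is built.
    epsilon
        Variance floor added before the square root.
    affine
        Whether a learnable per-channel scale and shift follow.
    """

    kind: str = "group"
    num_groups: int = 32
    epsilon: float = 1e-5
    affine: bool = True

    def __post_init__(self):
        if self.kind not in ("group", "batch"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        if self.num_groups < 1:
            raise ValueError("num_groups must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


class GroupNorm(Module):
    def __init__(self, channels: int, spec: NormSpec = NormSpec()):
        super().__init__()
        groups = min(spec.num_groups, channels)
        if channels % groups:
            raise ValueError(f"{channels} channels not divisible by {groups} groups")
        self.groups = groups
        self.eps = spec.epsilon
        self.affine = spec.affine
        if spec.affine:
            self.scale = Parameter(np.ones(channels))
            self.shift = Parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        N, C, H, W = x.shape
        xr = x.reshape(N, self.groups, (C // self.groups) * H * W)
        mu = xr.mean(axis=2, keepdims=True)
        xc = xr - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        out = xn.reshape(N, C, H, W)
        if self.affine:
            out = out * self.scale.reshape(1, C, 1, 1) + self.shift.reshape(1, C, 1, 1)
        return out


class BatchNorm2d(Module):
    """Across-batch normalization with running statistics for eval mode.

    ``frozen=True`` always applies the stored running statistics (the
    behaviour of a pretrained, untrained batch-norm layer).
    """

    def __init__(self, channels: int, spec: NormSpec = NormSpec(kind="batch"),
                 momentum: float = 0.1, frozen: bool = False):
        super().__init__()
        self.eps = spec.epsilon
        self.momentum = momentum
        self.frozen = frozen
        self.affine = spec.affine
        if spec.affine:
            self.scale = Parameter(np.ones(channels))
            self.shift = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._buffers = ("running_mean", "running_var")

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        N, C, H, W = x.shape
        if self.training and not self.frozen:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C)
            out = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            var = self.running_var.reshape(1, C, 1, 1)
            out = (x - as_tensor(mu)) * ((as_tensor(var) + self.eps) ** -0.5)
        if self.affine:
            out = out * self.scale.reshape(1, C, 1, 1) + self.shift.reshape(1, C, 1, 1)
        return out


def make_norm(channels: int, spec: NormSpec) -> Module:
    if spec.kind == "group":
        return GroupNorm(channels, spec)
    return BatchNorm2d(channels, spec)


def normalize(features: np.ndarray, spec: NormSpec, mode: str = "train") -> np.ndarray:
    """Functional normalization of a ``(N, C, H, W)`` batch.

    Applies the statistics-only transform (no learnable scale/shift).
    ``mode`` is ``"train"`` or ``"eval"``; it matters only for the batch
    kind, where eval mode uses the running averages.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 4:
        raise ValueError("expected a (N, C, H, W) batch")
    layer = make_norm(features.shape[1],
                      NormSpec(spec.kind, spec.num_groups, spec.epsilon, affine=False))
    if mode == "eval":
        layer.eval()
    out = layer(Tensor(features))
    return out.data
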