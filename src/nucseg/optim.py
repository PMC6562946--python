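"""Gradient-clipped AMSGrad optimizer.

AMSGrad is the maximum-bound correction of the adaptive-moment (Adam)
update: the second-moment estimate used in the denominator is the
running elementwise maximum, which keeps the effective step size
non-increasing per coordinate.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter

__all__ = ["AMSGrad", "clip_grad_norm"]


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class AMSGrad:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> float:
        """Apply one update; returns the pre-clip gradient norm."""
        norm = clip_grad_norm(self.params, self.clip_norm) if self.clip_norm \
            else float(np.sqrt(sum(float((p.grad ** 2).sum())
                                   for p in self.params if p.grad is not None)))
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            self.vhat[i] = np.maximum(self.vhat[i], self.v[i])
            mhat = self.m[i] / bias1
            vhat = self.vhat[i] / bias2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return norm

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        out = {"t": np.array(self.t)}
        for i in range(len(self.params)):
            out[f"m.{i}"] = self.m[i]
            out[f"v.{i}"] = self.v[i]
            out[f"vhat.{i}"] = self.vhat[i]
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m.{i}"], dtype=np.float64).copy()
            self.v[i] = np.asarray(state[f"v.{i}"], dtype=np.float64).copy()
            self.vhat[i] = np.asarray(state[f"vhat.{i}"], dtype=np.float64).copy()
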