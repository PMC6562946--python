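"""Neural-network layers on top of the autodiff engine.

Convolutions are evaluated by im2col (patch gathering followed by one
matrix product), which supports stride and dilation uniformly and keeps
the backward pass exact.  Layout convention is ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


# ---------------------------------------------------------------------------
# functional ops with custom gradients
# ---------------------------------------------------------------------------

def _im2col_indices(H, W, k, stride, dilation, pad):
    span = dilation * (k - 1) + 1
    Ho = (H + 2 * pad - span) // stride + 1
    Wo = (W + 2 * pad - span) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError(f"input {H}x{W} too small for kernel span {span}")
    i0 = dilation * np.repeat(np.arange(k), k)
    j0 = dilation * np.tile(np.arange(k), k)
    i1 = stride * np.repeat(np.arange(Ho), Wo)
    j1 = stride * np.tile(np.arange(Wo), Ho)
    rows = i0[:, None] + i1[None, :]          # (k*k, Ho*Wo)
    cols = j0[:, None] + j1[None, :]
    return rows, cols, Ho, Wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, dilation: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) with dilation support."""
    N, C, H, W = x.data.shape
    O, Ci, k, k2 = weight.data.shape
    assert Ci == C and k == k2
    rows, cols, Ho, Wo = _im2col_indices(H, W, k, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    patches = xp[:, :, rows, cols]                      # (N, C, k*k, L)
    pmat = patches.reshape(N, C * k * k, -1)            # (N, CKK, L)
    wmat = weight.data.reshape(O, C * k * k)
    out_data = np.einsum("ok,nkl->nol", wmat, pmat).reshape(N, O, Ho, Wo)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, req, parents=parents)

    def bw(g):
        gl = g.reshape(N, O, -1)
        if weight.requires_grad:
            gw = np.einsum("nol,nkl->ok", gl, pmat).reshape(O, C, k, k)
            weight.accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias.accumulate(gl.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.einsum("ok,nol->nkl", wmat, gl).reshape(N, C, k * k, -1)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), slice(None), rows, cols), gp)
            if padding:
                gxp = gxp[:, :, padding:padding + H, padding:padding + W]
            x.accumulate(gxp)
    out._backward_fn = bw
    return out


def max_pool2d(x: Tensor, k: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping max pooling; spatial size must be divisible by k."""
    stride = stride or k
    assert stride == k, "only non-overlapping pooling is supported"
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial size {H}x{W} not divisible by pool {k}")
    xr = x.data.reshape(N, C, H // k, k, W // k, k)
    out_data = xr.max(axis=(3, 5))
    out = Tensor(out_data, x.requires_grad, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        mask = xr == out_data[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / counts)
        x.accumulate(gx.reshape(N, C, H, W))
    out._backward_fn = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(out_data, x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            gx = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
            x.accumulate(gx)
    out._backward_fn = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy; ``labels`` are 0-based class indices."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    ll = np.log(p[np.arange(n), labels] + 1e-300)
    out = Tensor(-ll.mean(), logits.requires_grad, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            gz = p.copy()
            gz[np.arange(n), labels] -= 1.0
            logits.accumulate(g * gz / n)
    out._backward_fn = bw
    return out


def sigmoid_bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, numerically stable."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    out = Tensor(loss.mean(), logits.requires_grad, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                           np.exp(z) / (1.0 + np.exp(z)))
            logits.accumulate(g * (sig - t) / n)
    out._backward_fn = bw
    return out


# ---------------------------------------------------------------------------
# module containers
# ---------------------------------------------------------------------------

def _walk_children(obj, prefix):
    """Yield (name, value) for parameters/modules, recursing into lists."""
    if isinstance(obj, (Parameter, Module)):
        yield prefix, obj
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            yield from _walk_children(item, f"{prefix}.{i}")


class Module:
    """Base class: parameter discovery, state dicts, train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, v in self.__dict__.items():
            yield from _walk_children(v, name)

    def modules(self):
        yield self
        for _, child in self._children():
            if isinstance(child, Module):
                yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, child in self._children():
            if isinstance(child, Parameter):
                yield f"{prefix}{name}", child
            else:
                yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_name, buf_name, buf in self._named_buffers():
            state[f"{m_name}{buf_name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for m_name, buf_name, _ in self._named_buffers():
            key = f"{m_name}{buf_name}"
            if key in state:
                self._set_buffer(m_name, buf_name, state[key])

    # buffers (batch-norm running stats) are registered by name walks
    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children():
            if isinstance(child, Module):
                yield from child._named_modules(f"{prefix}{name}.")

    def _named_buffers(self):
        for mod_prefix, mod in self._named_modules():
            for buf_name in getattr(mod, "_buffers", ()):
                yield mod_prefix, buf_name, getattr(mod, buf_name)

    def _set_buffer(self, path: str, buf_name: str, value) -> None:
        for mod_prefix, mod in self._named_modules():
            if mod_prefix == path:
                setattr(mod, buf_name, np.asarray(value, dtype=np.float64).copy())
                return
        raise KeyError(f"no module at {path!r}")


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def __call__(self, x):
        return x.relu()


class Conv2d(Module):
    """Convolution layer with He-normal initialization."""

    def __init__(self, in_channels, out_channels, kernel, stride=1,
                 dilation=1, padding="same", bias=True, rng=None, init_scale=1.0):
        super().__init__()
        if kernel % 2 == 0 and padding == "same":
            raise ValueError("'same' padding requires an odd kernel")
        self.stride = stride
        self.dilation = dilation
        self.padding = dilation * (kernel - 1) // 2 if padding == "same" else int(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        std = init_scale * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, dilation=self.dilation, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None, init_scale=1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = init_scale * np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x):
        return x @ self.weight + self.bias
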