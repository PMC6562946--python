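"""Stochastic paired image/annotation augmentation with replayable records.

Eight transforms: sharpening, Gaussian noise, grayscale conversion,
contrast/brightness adjustment, random scaling, rotation, flip, and
channel rearrangement.  A random subset (1-3 transforms) is drawn and
superimposed in a drawn order; geometric transforms are applied
identically to the label map with nearest-neighbor interpolation, while
photometric transforms never touch the labels.  Every call returns an
:class:`AugmentationRecord` whose replay on the same input reproduces
the output bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .synthetic import InstanceLabelMap, as_label_map

logger = logging.getLogger(__name__)

__all__ = ["AugmentationRecord", "random_augment", "replay",
           "TRANSFORM_NAMES", "record_to_text", "record_from_text"]

TRANSFORM_NAMES = (
    "sharpen", "gauss_noise", "grayscale", "contrast_brightness",
    "scale", "rotate", "flip", "channel_shuffle",
)

_GEOMETRIC = {"scale", "rotate", "flip"}


@dataclass(frozen=True)
class AugmentationRecord:
    """Ordered, replayable log of the applied transforms."""

    steps: tuple = field(default_factory=tuple)  # (name, params-dict) pairs


def _as_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# individual transforms (image uint8 HxWx3, labels int32 HxW)
# ---------------------------------------------------------------------------

def _apply_sharpen(image, labels, params):
    amount = params["amount"]
    blurred = ndi.gaussian_filter(image.astype(np.float64), sigma=(1.0, 1.0, 0))
    out = image.astype(np.float64) + amount * (image.astype(np.float64) - blurred)
    return _as_uint8(out), labels


def _apply_gauss_noise(image, labels, params):
    rng = np.random.default_rng(params["sub_seed"])
    noise = rng.normal(0.0, params["sigma"], size=image.shape)
    return _as_uint8(image.astype(np.float64) + noise), labels


def _apply_grayscale(image, labels, params):
    lum = (0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2])
    return _as_uint8(np.stack([lum] * 3, axis=-1)), labels


def _apply_contrast_brightness(image, labels, params):
    alpha, beta = params["alpha"], params["beta"]
    out = alpha * (image.astype(np.float64) - 127.5) + 127.5 + beta
    return _as_uint8(out), labels


def _apply_scale(image, labels, params):
    """Zoom about the center, then crop or pad back to the original size."""
    factor = params["factor"]
    H, W = labels.shape
    img = ndi.zoom(image.astype(np.float64), (factor, factor, 1), order=1)
    lab = ndi.zoom(labels, (factor, factor), order=0)
    out_img = np.zeros((H, W, 3))
    out_lab = np.zeros((H, W), dtype=labels.dtype)
    h, w = lab.shape
    if factor >= 1.0:
        y0, x0 = (h - H) // 2, (w - W) // 2
        out_img = img[y0:y0 + H, x0:x0 + W]
        out_lab = lab[y0:y0 + H, x0:x0 + W]
    else:
        y0, x0 = (H - h) // 2, (W - w) // 2
        out_img[y0:y0 + h, x0:x0 + w] = img
        out_lab[y0:y0 + h, x0:x0 + w] = lab
    return _as_uint8(out_img), out_lab


def _apply_rotate(image, labels, params):
    k = params["k"]  # multiples of 90 degrees, counter-clockwise
    return np.rot90(image, k, axes=(0, 1)).copy(), np.rot90(labels, k, axes=(0, 1)).copy()


def _apply_flip(image, labels, params):
    axis = params["axis"]  # 0 vertical (rows), 1 horizontal (cols)
    return np.flip(image, axis=axis).copy(), np.flip(labels, axis=axis).copy()


def _apply_channel_shuffle(image, labels, params):
    perm = list(params["perm"])
    return image[..., perm].copy(), labels


_APPLY = {
    "sharpen": _apply_sharpen,
    "gauss_noise": _apply_gauss_noise,
    "grayscale": _apply_grayscale,
    "contrast_brightness": _apply_contrast_brightness,
    "scale": _apply_scale,
    "rotate": _apply_rotate,
    "flip": _apply_flip,
    "channel_shuffle": _apply_channel_shuffle,
}


def _draw_params(name: str, rng) -> dict:
    if name == "sharpen":
        return {"amount": float(np.round(rng.uniform(0.3, 1.2), 4))}
    if name == "gauss_noise":
        return {"sigma": float(np.round(rng.uniform(2.0, 8.0), 4)),
                "sub_seed": int(rng.integers(0, 2 ** 31 - 1))}
    if name == "grayscale":
        return {}
    if name == "contrast_brightness":
        return {"alpha": float(np.round(rng.uniform(0.7, 1.3), 4)),
                "beta": float(np.round(rng.uniform(-25, 25), 4))}
    if name == "scale":
        return {"factor": float(np.round(rng.uniform(0.8, 1.25), 4))}
    if name == "rotate":
        return {"k": int(rng.integers(1, 4))}
    if name == "flip":
        return {"axis": int(rng.integers(0, 2))}
    if name == "channel_shuffle":
        perms = [(0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
        return {"perm": perms[int(rng.integers(0, len(perms)))]}
    raise KeyError(name)


def random_augment(image: np.ndarray, labels, seed: int):
    """Apply 1-3 randomly drawn transforms; returns (image, labels, record)."""
    labels = as_label_map(labels)
    if image.shape[:2] != labels.shape:
        raise ValueError("image and labels must share spatial size")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 4))
    chosen = rng.choice(len(TRANSFORM_NAMES), size=n, replace=False)
    steps = tuple((TRANSFORM_NAMES[i], _draw_params(TRANSFORM_NAMES[i], rng))
                  for i in chosen)
    record = AugmentationRecord(steps=steps)
    out_image, out_labels = replay(image, labels, record)
    return out_image, out_labels, record


def replay(image: np.ndarray, labels, record: AugmentationRecord):
    """Deterministically re-apply a recorded transform sequence."""
    labels = as_label_map(labels)
    img, lab = image.copy(), labels.grid.copy()
    before_ids = set(labels.ids)
    for name, params in record.steps:
        if name not in _APPLY:
            raise KeyError(f"unknown transform {name!r}")
        img, lab = _APPLY[name](img, lab, params)
    lost = before_ids - set(np.unique(lab).tolist())
    if lost:
        logger.warning("augmentation dropped %d instance(s) reduced to 0 px: %s",
                       len(lost), sorted(lost))
    return img, InstanceLabelMap(lab)


# ---------------------------------------------------------------------------
# structured-text serialization
# ---------------------------------------------------------------------------

def record_to_text(record: AugmentationRecord) -> str:
    lines = []
    for name, params in record.steps:
        kv = " ".join(f"{k}={_fmt(v)}" for k, v in sorted(params.items()))
        lines.append(f"{name} {kv}".rstrip())
    return "\n".join(lines) + ("\n" if lines else "")


def _fmt(v):
    if isinstance(v, tuple):
        return ",".join(str(x) for x in v)
    return repr(v)


def record_from_text(text: str) -> AugmentationRecord:
    steps = []
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split()
        name, params = parts[0], {}
        for tok in parts[1:]:
            k, v = tok.split("=", 1)
            if "," in v:
                params[k] = tuple(int(x) for x in v.split(","))
            else:
                try:
                    params[k] = int(v)
                except ValueError:
                    params[k] = float(v)
        steps.append((name, params))
    return AugmentationRecord(steps=tuple(steps))
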