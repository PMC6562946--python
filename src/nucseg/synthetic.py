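"""Seeded synthetic dense-nuclei scenes with instance ground truth.

Emulates the regime of public nucleus-segmentation benchmarks: many
small blob-like instances per image (dense scenes exceed 25), instance
areas down to ~21 px, adhering/overlapping placements, and two imaging
modes — brightfield H&E-like (dark blue-purple nuclei on pink cytoplasm
and grey-blue matrix) and fluorescence (bright blobs on a dark, noisy
background).

Nuclei are ellipses with low-frequency radial boundary jitter.  Overlap
is resolved by placement order (a later instance occludes earlier ones)
so the label map remains a partition, which both evaluation metrics
assume.  Identical specs (including the seed) produce bitwise-identical
scenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SceneSpec", "SyntheticScene", "InstanceLabelMap", "PlacementError",
    "generate_scene", "write_instance_layout", "read_instance_layout",
    "scene_statistics", "SceneStatistics", "canonicalize_labels",
    "write_label_map", "read_label_map", "sample_scene_specs",
]

# H&E-like palette (RGB, 8-bit): fixed constants, jittered per nucleus
_BRIGHTFIELD_CYTOPLASM = np.array([231, 180, 200], dtype=np.float64)  # pink
_BRIGHTFIELD_MATRIX = np.array([176, 188, 212], dtype=np.float64)     # grey-blue
_BRIGHTFIELD_NUCLEUS = np.array([72, 58, 128], dtype=np.float64)      # dark blue-purple
_FLUOR_TINT = np.array([0.45, 1.0, 0.65], dtype=np.float64)


class PlacementError(RuntimeError):
    """Raised when the requested nucleus count cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} nuclei within the retry budget; "
            f"achieved {achieved}")


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic scene."""

    image_height: int = 256
    image_width: int = 256
    n_nuclei: int = 40
    mode: str = "brightfield"
    radius_range: tuple[float, float] = (4.0, 10.0)
    max_overlap_fraction: float = 0.3
    min_instance_area: int = 21
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("radius_range must be a positive (min, max) interval")
        if not 0.0 <= self.max_overlap_fraction <= 1.0:
            raise ValueError("max_overlap_fraction must lie in [0, 1]")
        if self.min_instance_area < 1:
            raise ValueError("min_instance_area must be >= 1")
        if self.mode not in ("brightfield", "fluorescence"):
            raise ValueError(f"unknown imaging mode {self.mode!r}")


class InstanceLabelMap:
    """2-D integer grid assigning each pixel to one instance (0 = background)."""

    def __init__(self, grid: np.ndarray):
        grid = np.asarray(grid)
        if grid.ndim != 2 or not np.issubdtype(grid.dtype, np.integer):
            raise ValueError("label map must be a 2-D integer grid")
        if grid.min() < 0:
            raise ValueError("labels must be non-negative")
        self.grid = grid.astype(np.int32)

    @property
    def shape(self):
        return self.grid.shape

    @property
    def ids(self) -> list[int]:
        vals = np.unique(self.grid)
        return [int(v) for v in vals if v != 0]

    def __eq__(self, other):
        return isinstance(other, InstanceLabelMap) and np.array_equal(self.grid, other.grid)

    def mask(self, instance_id: int) -> np.ndarray:
        return self.grid == instance_id

    def canonicalized(self) -> "InstanceLabelMap":
        return InstanceLabelMap(canonicalize_labels(self.grid))


def canonicalize_labels(grid: np.ndarray) -> np.ndarray:
    """Relabel instances 1..n ordered by first (row-major) pixel occurrence."""
    grid = np.asarray(grid)
    flat = grid.ravel()
    nonzero = flat[flat != 0]
    if nonzero.size == 0:
        return grid.astype(np.int32)
    _, first_pos = np.unique(nonzero, return_index=True)
    order = np.argsort(first_pos)               # ids by first appearance
    old_ids = np.unique(nonzero)[order]
    mapping = np.zeros(int(grid.max()) + 1, dtype=np.int32)
    mapping[old_ids] = np.arange(1, len(old_ids) + 1)
    return mapping[grid]


@dataclass
class SyntheticScene:
    image: np.ndarray                 # H x W x 3 uint8
    labels: InstanceLabelMap
    provenance: SceneSpec
    centers: list = field(default_factory=list)


def as_label_map(labels) -> InstanceLabelMap:
    return labels if isinstance(labels, InstanceLabelMap) else InstanceLabelMap(labels)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _ellipse_mask(H, W, cy, cx, ry, rx, phi, jitter_amp, jitter_phase):
    """Rasterize one boundary-jittered ellipse as a boolean mask."""
    rmax = max(ry, rx) * (1.0 + jitter_amp.sum()) + 1.0
    y0, y1 = int(max(0, np.floor(cy - rmax))), int(min(H, np.ceil(cy + rmax) + 1))
    x0, x1 = int(max(0, np.floor(cx - rmax))), int(min(W, np.ceil(cx + rmax) + 1))
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    theta = np.arctan2(v, u)
    boundary = 1.0
    for m, (amp, ph) in enumerate(zip(jitter_amp, jitter_phase), start=2):
        boundary = boundary + amp * np.cos(m * theta + ph)
    local = rho <= boundary
    mask = np.zeros((H, W), dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one scene; raises :class:`PlacementError` if packing fails."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    grid = np.zeros((H, W), dtype=np.int32)
    placed = []
    retry_budget = 200
    for k in range(1, spec.n_nuclei + 1):
        ok = False
        for _ in range(retry_budget):
            rmin, rmax = spec.radius_range
            ry = rng.uniform(rmin, rmax)
            rx = ry * rng.uniform(0.6, 1.0)       # mild eccentricity
            margin = max(ry, rx) * 0.5
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            phi = rng.uniform(0, np.pi)
            jitter_amp = rng.uniform(0.0, 0.08, size=2)
            jitter_phase = rng.uniform(0, 2 * np.pi, size=2)
            mask = _ellipse_mask(H, W, cy, cx, ry, rx, phi, jitter_amp, jitter_phase)
            if mask is None:
                continue
            area = int(mask.sum())
            if area < spec.min_instance_area:
                continue
            overlap = int((mask & (grid > 0)).sum())
            if area > 0 and overlap / area > spec.max_overlap_fraction:
                continue
            # later instance occludes; earlier instances must survive
            occluded = grid[mask]
            touched = np.unique(occluded[occluded > 0])
            survive = True
            for t in touched:
                if int(((grid == t) & ~mask).sum()) < spec.min_instance_area:
                    survive = False
                    break
            if not survive:
                continue
            grid[mask] = k
            placed.append((cy, cx, ry, rx, k))
            ok = True
            break
        if not ok:
            raise PlacementError(spec.n_nuclei, k - 1)

    grid = canonicalize_labels(grid)
    image = _render(grid, placed, spec, rng)
    return SyntheticScene(image=image, labels=InstanceLabelMap(grid),
                          provenance=spec, centers=[(c[0], c[1]) for c in placed])


def _render(grid, placed, spec, rng):
    H, W = grid.shape
    if spec.mode == "brightfield":
        img = np.tile(_BRIGHTFIELD_CYTOPLASM, (H, W, 1))
        # low-frequency grey-blue matrix patches
        n_patch = max(1, (H * W) // 8192)
        for _ in range(n_patch):
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            r = rng.uniform(0.1, 0.25) * min(H, W)
            yy, xx = np.mgrid[0:H, 0:W]
            w = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r * r)))
            img = img * (1 - 0.5 * w[..., None]) + _BRIGHTFIELD_MATRIX * 0.5 * w[..., None]
        for instance_id in np.unique(grid[grid > 0]):
            mask = grid == instance_id
            color = _BRIGHTFIELD_NUCLEUS + rng.uniform(-14, 14, size=3)
            img[mask] = color
        img += rng.normal(0, 4.0, size=img.shape)
    else:
        img = np.full((H, W, 3), 8.0)
        base = np.zeros((H, W))
        for instance_id in np.unique(grid[grid > 0]):
            mask = grid == instance_id
            peak = rng.uniform(170, 240)
            # radial falloff from instance centroid gives a soft blob profile
            ys, xs = np.nonzero(mask)
            cy, cx = ys.mean(), xs.mean()
            d = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2)
            dmax = d.max() if d.max() > 0 else 1.0
            base[ys, xs] = peak * (1.0 - 0.45 * (d / dmax) ** 2)
        img += base[..., None] * _FLUOR_TINT
        img += rng.normal(0, 3.0, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def sample_scene_specs(n_scenes: int, seed: int, *, size: int = 64,
                       n_range: tuple[int, int] = (5, 10), mode: str = "fluorescence",
                       radius_range: tuple[float, float] = (4.0, 7.0),
                       max_overlap_fraction: float = 0.0,
                       min_instance_area: int = 12) -> list[SceneSpec]:
    """Draw a reproducible batch of scene specs (nucleus count varies per scene)."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_scenes):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        specs.append(SceneSpec(size, size, n, mode, radius_range,
                               max_overlap_fraction, min_instance_area,
                               seed=int(rng.integers(0, 2 ** 31 - 1))))
    return specs


# ---------------------------------------------------------------------------
# standard annotation layouts
# ---------------------------------------------------------------------------

def write_instance_layout(scene: SyntheticScene | tuple, root, *,
                          overwrite: bool = False) -> list[str]:
    """Write ``image.png`` plus one binary mask PNG per instance under ``masks/``.

    Returns the manifest (relative file paths), which is also written to
    ``manifest.txt``.  Refuses a colliding non-empty directory unless
    ``overwrite`` is set.
    """
    if isinstance(scene, SyntheticScene):
        image, labels = scene.image, scene.labels
    else:
        image, labels = scene
        labels = as_label_map(labels)
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} exists and is not empty (pass overwrite=True)")
    (root / "masks").mkdir(parents=True, exist_ok=True)
    iio.imwrite(root / "image.png", image)
    manifest = ["image.png"]
    for instance_id in labels.ids:
        name = f"masks/mask_{instance_id:04d}.png"
        iio.imwrite(root / name, (labels.mask(instance_id) * np.uint8(255)))
        manifest.append(name)
    (root / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return manifest


def read_instance_layout(root) -> InstanceLabelMap:
    """Merge per-instance mask PNGs back into one label map.

    Masks are merged in manifest order (or sorted filename order when no
    manifest is present); a pixel claimed by several masks is owned by
    the first-listed one, with a logged warning.
    """
    root = Path(root)
    image_path = root / "image.png"
    if not image_path.exists():
        candidates = sorted(p for p in root.iterdir()
                            if p.suffix.lower() in (".png", ".tif", ".tiff") and p.is_file())
        if not candidates:
            raise FileNotFoundError(f"no image file under {root}")
        image_path = candidates[0]
    image = iio.imread(image_path)
    H, W = image.shape[:2]
    mask_dir = root / "masks"
    if not mask_dir.is_dir():
        raise FileNotFoundError(f"missing masks/ directory under {root}")
    manifest_path = root / "manifest.txt"
    if manifest_path.exists():
        names = [line for line in manifest_path.read_text().splitlines()
                 if line.startswith("masks/")]
        mask_files = [root / n for n in names]
    else:
        mask_files = sorted(mask_dir.iterdir())
    grid = np.zeros((H, W), dtype=np.int32)
    for k, path in enumerate(mask_files, start=1):
        m = iio.imread(path)
        if m.ndim == 3:
            m = m[..., 0]
        if m.shape != (H, W):
            raise ValueError(f"mask {path.name} shape {m.shape} != image shape {(H, W)}")
        fg = m > 0
        clash = fg & (grid > 0)
        if clash.any():
            logger.warning("mask %s overlaps %d already-claimed pixels; "
                           "first-listed mask keeps them", path.name, int(clash.sum()))
            fg &= grid == 0
        grid[fg] = k
    return InstanceLabelMap(grid)


def write_label_map(labels, path) -> None:
    """Write a label map as one 16-bit PNG (0 = background)."""
    labels = as_label_map(labels)
    if labels.grid.max() > 65535:
        raise ValueError("too many instances for a 16-bit label map")
    iio.imwrite(Path(path), labels.grid.astype(np.uint16))


def read_label_map(path) -> InstanceLabelMap:
    return InstanceLabelMap(iio.imread(Path(path)).astype(np.int32))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class SceneStatistics:
    count: int
    areas: dict[int, int]
    min_area: int | None
    max_area: int | None
    adjacency_count: int


def scene_statistics(labels) -> SceneStatistics:
    """Instance count, per-instance areas, and touching-instance pairs.

    Adjacency counts unordered pairs of distinct instances with at least
    one 4-connected pixel contact — a proxy for adhering nuclei.
    """
    labels = as_label_map(labels)
    grid = labels.grid
    ids, counts = np.unique(grid[grid > 0], return_counts=True)
    areas = {int(i): int(c) for i, c in zip(ids, counts)}
    pairs = set()
    for a, b in ((grid[:, :-1], grid[:, 1:]), (grid[:-1, :], grid[1:, :])):
        touch = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[touch].ravel(), b[touch].ravel()):
            pairs.add((min(int(u), int(v)), max(int(u), int(v))))
    return SceneStatistics(
        count=len(areas),
        areas=areas,
        min_area=min(areas.values()) if areas else None,
        max_area=max(areas.values()) if areas else None,
        adjacency_count=len(pairs),
    )
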