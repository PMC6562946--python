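import numpy as np
import pytest

from nucseg import synthetic as S


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_scene():
    """Small fluorescence scene with well-separated nuclei."""
    spec = S.SceneSpec(64, 64, 6, "fluorescence", (4.0, 7.0), 0.0, 12, seed=3)
    return S.generate_scene(spec)


@pytest.fixture(scope="session")
def brightfield_scene():
    spec = S.SceneSpec(128, 128, 14, "brightfield", (4.0, 9.0), 0.3, 21, seed=5)
    return S.generate_scene(spec)


def random_label_map(rng, shape=(32, 32), n_instances=5, min_side=2, max_side=8):
    """Random rectangle-instance label map (later rectangles occlude)."""
    grid = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_instances + 1):
        h = int(rng.integers(min_side, max_side + 1))
        w = int(rng.integers(min_side, max_side + 1))
        y = int(rng.integers(0, shape[0] - h + 1))
        x = int(rng.integers(0, shape[1] - w + 1))
        grid[y:y + h, x:x + w] = k
    return S.canonicalize_labels(grid)


@pytest.fixture
def label_map_factory():
    return random_label_map
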