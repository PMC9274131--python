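import numpy as np
import pytest

from trapscan.pipeline import PipelineConfig, train_synthetic_model
from trapscan.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_model(config):
    """A quickly trained classifier shared by the pipeline-level tests."""
    return train_synthetic_model(n_per_class=60, config=config, seed=11)


@pytest.fixture(scope="session")
def default_scene():
    spec = SceneSpec(seed=5)
    image, annotations = generate_scene(spec)
    return spec, image, annotations


def planted_gray_block(
    rng,
    n_blobs: int = 3,
    area_range: tuple[float, float] = (8.0, 20.0),
    contrast: float = 60.0,
    background: float = 200.0,
    noise_sd: float = 2.0,
    size: int = 64,
):
    """A grayscale block with circular blobs of known centers and areas.

    Returns (block, truths) where truths is a list of (cx, cy, area).
    Blobs are darker or brighter than the background at the given contrast.
    """
    img = np.full((size, size), background, dtype=float)
    yy, xx = np.mgrid[0:size, 0:size]
    truths = []
    for _ in range(n_blobs):
        for _attempt in range(500):
            area = rng.uniform(*area_range)
            r = np.sqrt(area / np.pi)
            cx, cy = rng.uniform(r + 3, size - r - 3, 2)
            if all((cx - tx) ** 2 + (cy - ty) ** 2 > 100 for tx, ty, _ in truths):
                break
        else:
            continue
        coverage = np.clip(r + 0.5 - np.hypot(xx - cx, yy - cy), 0, 1)
        level = background + rng.choice([-1.0, 1.0]) * contrast
        img = img * (1 - coverage) + coverage * level
        truths.append((cx, cy, area))
    img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, 255)
    return img, truths
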