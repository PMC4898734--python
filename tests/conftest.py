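import numpy as np
import pytest

from pollenvision.dataset_io import SegmentedPollenImage
from pollenvision.synthetic_data import (
    SyntheticClassSpec,
    default_class_specs,
    generate_dataset,
)


def disk_mask(radius: int, canvas: int | None = None) -> np.ndarray:
    canvas = canvas or (2 * radius + 21)
    c = canvas // 2
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipse_mask(a: int, b: int, canvas: int | None = None) -> np.ndarray:
    canvas = canvas or (2 * max(a, b) + 21)
    c = canvas // 2
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    return ((yy - c) / b) ** 2 + ((xx - c) / a) ** 2 <= 1.0


def square_mask(side: int, margin: int = 10) -> np.ndarray:
    canvas = side + 2 * margin
    m = np.zeros((canvas, canvas), dtype=bool)
    m[margin:margin + side, margin:margin + side] = True
    return m


def noisy_image(mask: np.ndarray, seed: int = 0,
                mean: float = 120.0, sigma: float = 25.0) -> SegmentedPollenImage:
    rng = np.random.default_rng(seed)
    pixels = np.full(mask.shape + (3,), 255, dtype=float)
    vals = rng.normal(mean, sigma, size=mask.shape + (3,))
    pixels[mask] = vals[mask]
    return SegmentedPollenImage(
        pixels=np.clip(pixels, 0, 255).astype(np.uint8),
        mask=mask, label="test", source_id="synthetic",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """3 well-separated classes x 9 images at a small canvas (fast)."""
    return generate_dataset(default_class_specs(3), n_per_class=9,
                            canvas=160, seed=11)


@pytest.fixture(scope="session")
def study_dataset():
    """The emulated study conditions: 5 separable classes x 35 images, 256 px."""
    return generate_dataset(default_class_specs(5), n_per_class=35,
                            canvas=256, seed=101)


@pytest.fixture(scope="session")
def star_spec():
    return SyntheticClassSpec(
        name="star", base_shape="star", radius=60,
        spike_count=12, spike_depth=0.4, jitter=0.0,
    )
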