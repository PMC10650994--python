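import numpy as np
import pytest
from PIL import Image

from leafcgsd.imaging import CanopyImage


def random_canopy(rng: np.random.Generator, height: int = 24, width: int = 24,
                  mask_fraction: float = 0.6) -> CanopyImage:
    """Random RGB image with a random foreground mask (at least one pixel)."""
    rgb = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    mask = rng.random((height, width)) < mask_fraction
    if not mask.any():
        mask[height // 2, width // 2] = True
    return CanopyImage(rgb=rgb, mask=mask)


def write_rgba_png(path, rgb: np.ndarray, alpha: np.ndarray) -> None:
    rgba = np.dstack([rgb.astype(np.uint8), alpha.astype(np.uint8)])
    Image.fromarray(rgba, mode="RGBA").save(path)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230815)


@pytest.fixture
def canopy_png(tmp_path, rng):
    """A 10x10 RGBA PNG with 40 opaque pixels; returns (path, rgb, alpha)."""
    rgb = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
    alpha = np.zeros((10, 10), dtype=np.uint8)
    flat = rng.choice(100, size=40, replace=False)
    alpha.flat[flat] = 255
    path = tmp_path / "canopy.png"
    write_rgba_png(path, rgb, alpha)
    return path, rgb, alpha
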