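"""Masked canopy images, per-channel gradation arrays and cumulative curves.

A canopy photograph arrives with its background removed: an RGBA PNG whose
transparent pixels are background.  All downstream statistics are computed on
the foreground (leaf) pixels only.  For each of the R, G, B channels and the
derived gray level Y, the 256-bin histogram of foreground intensities is the
"gradation array"; its normalized prefix sum is the cumulative gradation
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CHANNELS",
    "GRAY_WEIGHTS",
    "CanopyImage",
    "GradationArray",
    "CumulativeCurve",
    "ImageFormatError",
    "EmptyForegroundError",
    "load_masked_image",
    "gray_channel",
    "gradation_array",
    "cumulative_curve",
]

CHANNELS = ("R", "G", "B", "Y")

#: ITU-R BT.601 luma weights, the MATLAB ``rgb2gray`` convention.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


class ImageFormatError(ValueError):
    """Input file is not a PNG or cannot be decoded."""


class EmptyForegroundError(ValueError):
    """No foreground (non-transparent) pixel; statistics are undefined."""


@dataclass
class CanopyImage:
    """Background-removed canopy image: RGB planes plus a foreground mask."""

    rgb: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True = foreground
    path: str | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must be (H, W, 3), got {self.rgb.shape}")
        if self.mask.shape != self.rgb.shape[:2]:
            raise ValueError("mask shape does not match image")
        if not self.mask.any():
            raise EmptyForegroundError("image has no foreground pixel")

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def channel_values(self, channel: str) -> np.ndarray:
        """Foreground intensities (1-D uint8 array) for one of R, G, B, Y."""
        if channel == "Y":
            return gray_channel(self)[self.mask]
        try:
            idx = "RGB".index(channel)
        except ValueError:
            raise ValueError(f"unknown channel {channel!r}") from None
        return self.rgb[:, :, idx][self.mask]


@dataclass
class GradationArray:
    """256-bin histogram of foreground intensities for one channel."""

    channel: str
    counts: np.ndarray  # (256,) int64
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ValueError("counts must have shape (256,)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n or self.n < 1:
            raise ValueError("sum(counts) must equal n >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": np.arange(256), "count": self.counts})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CumulativeCurve:
    """Cumulative relative frequency of gradation levels; ends at exactly 1."""

    channel: str
    frequencies: np.ndarray  # (256,) float, non-decreasing, last == 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (256,):
            raise ValueError("frequencies must have shape (256,)")
        if (np.diff(self.frequencies) < -1e-12).any():
            raise ValueError("cumulative curve must be non-decreasing")
        if abs(self.frequencies[-1] - 1.0) > 1e-12:
            raise ValueError("cumulative curve must end at 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": np.arange(256), "cumulative_frequency": self.frequencies}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_masked_image(path, alpha_threshold: int = 0) -> CanopyImage:
    """Load a background-removed PNG; alpha > ``alpha_threshold`` is foreground.

    Images without an alpha channel are taken as all-foreground.
    """
    try:
        img = Image.open(path)
    except Exception as exc:  # unreadable / not an image
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if img.format != "PNG":
        raise ImageFormatError(f"{path}: expected PNG, got {img.format}")
    rgba = np.asarray(img.convert("RGBA"))
    rgb = rgba[:, :, :3]
    if img.mode in ("RGBA", "LA", "PA") or "transparency" in img.info:
        mask = rgba[:, :, 3] > alpha_threshold
    else:
        mask = np.ones(rgb.shape[:2], dtype=bool)
    if not mask.any():
        raise EmptyForegroundError(f"{path}: no pixel with alpha > {alpha_threshold}")
    return CanopyImage(rgb=rgb, mask=mask, path=str(path))


def gray_channel(image: CanopyImage) -> np.ndarray:
    """Gray-level plane Y = round(0.2989 R + 0.5870 G + 0.1140 B).

    Rounding is half-away-from-zero (the MATLAB convention), not banker's
    rounding; for non-negative values this is ``floor(x + 0.5)``.
    """
    wr, wg, wb = GRAY_WEIGHTS
    planes = image.rgb.astype(np.float64)
    y = wr * planes[:, :, 0] + wg * planes[:, :, 1] + wb * planes[:, :, 2]
    return np.floor(y + 0.5).astype(np.uint8)


def gradation_array(image: CanopyImage, channel: str) -> GradationArray:
    """Histogram of foreground intensities for one channel (background excluded)."""
    values = image.channel_values(channel)
    counts = np.bincount(values, minlength=256)
    return GradationArray(channel=channel, counts=counts, n=int(values.size))


def cumulative_curve(g: GradationArray) -> CumulativeCurve:
    freqs = np.cumsum(g.counts) / g.n
    freqs[-1] = 1.0  # exact despite float accumulation
    return CumulativeCurve(channel=g.channel, frequencies=freqs)
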