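"""Sticky-paper region-of-interest extraction.

A trap photograph contains the bright (typically yellow) adhesive card plus
whatever background the camera saw.  The card is isolated by thresholding
the Cb (blue-difference chroma) plane: yellow card pixels have strongly
depressed Cb, so Otsu's method on that plane separates card from scene
regardless of overall brightness.  The binary image is hole-filled (insects
and glue spots punch dark holes through the chroma threshold), the largest
connected component is kept as the card, and the masked RGB image is the
RoI passed downstream.

Whether card pixels land above or below the Otsu threshold depends on the
card color and the scene, so both polarities are tried and the side whose
largest component is bigger wins; the choice is recorded on the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .colorspaces import rgb_to_ycbcr_u8

MIN_IMAGE_SIDE = 64


class NoTrapFoundError(ValueError):
    """Raised when no sufficiently large card-like component exists."""


class DegenerateHistogramError(ValueError):
    """Raised when a plane has a single gray level and cannot be thresholded."""


@dataclass
class TrapImage:
    """An 8-bit RGB trap photograph.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array in R, G, B order.
    source_path:
        Optional provenance of the raster.
    """

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"TrapImage needs an (H, W, 3) array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.height < MIN_IMAGE_SIDE or self.width < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}px, "
                f"got {self.height}x{self.width}"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @classmethod
    def load(cls, path: str | Path) -> "TrapImage":
        """Read a PNG/TIFF/JPEG file into a TrapImage (alpha discarded)."""
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        return cls(pixels=arr.astype(np.uint8), source_path=str(path))


@dataclass
class RoiMask:
    """Binary card mask plus the conjunction of mask and source image."""

    mask: np.ndarray
    roi_image: np.ndarray
    coverage_fraction: float
    polarity: str = "below"  # card pixels "below" or "above" the Cb threshold
    threshold: int = 0
    bbox: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))  # x0, y0, x1, y1

    def save_mask(self, path: str | Path) -> None:
        iio.imwrite(path, (self.mask.astype(np.uint8) * 255))

    def save_metadata(self, path: str | Path) -> None:
        meta = {
            "bbox": list(self.bbox),
            "coverage_fraction": self.coverage_fraction,
            "polarity": self.polarity,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(meta, indent=2))


def rgb_to_ycbcr(image: TrapImage) -> np.ndarray:
    """Return the 8-bit full-range BT.601 Y/Cb/Cr planes of a trap image."""
    return rgb_to_ycbcr_u8(image.pixels)


def otsu_threshold(plane: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit plane.

    Returns the integer level ``t`` maximizing the between-class variance of
    the split ``{<= t} / {> t}``; ties go to the lowest level.  A constant
    plane has no split and raises :class:`DegenerateHistogramError`.
    """
    plane = np.asarray(plane)
    values = np.clip(np.round(plane.astype(np.float64)), 0, 255).astype(np.intp)
    hist = np.bincount(values.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("plane has fewer than two gray levels")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    mean_all = m0[-1] / total
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / (total - w0)
        sigma_b = (w0 / total) * (1.0 - w0 / total) * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    # last level is an empty split; argmax breaks ties toward the lowest level
    return int(np.argmax(sigma_b[:-1]))


def _largest_component(binary: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.zeros_like(binary, dtype=bool), 0
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    return labels == best, int(sizes[best - 1])


def extract_roi(image: TrapImage, min_fraction: float = 0.05) -> RoiMask:
    """Locate the sticky card and mask everything else out.

    The Cb plane is Otsu-binarized, each polarity is hole-filled and reduced
    to its largest connected component, and the polarity with the larger
    component is kept.  Raises :class:`NoTrapFoundError` if the winning
    component covers less than ``min_fraction`` of the frame.
    """
    cb = rgb_to_ycbcr(image)[..., 1]
    t = otsu_threshold(cb)

    # polarity is judged on the raw components: hole-filling first would let
    # a background ring that encloses the card fill to the whole frame and win
    candidates = {}
    for polarity, binary in (("below", cb <= t), ("above", cb > t)):
        comp, size = _largest_component(binary)
        candidates[polarity] = (comp, size)
    polarity = max(candidates, key=lambda p: candidates[p][1])
    mask, _ = candidates[polarity]
    mask = ndimage.binary_fill_holes(mask)
    size = int(mask.sum())

    n_pixels = image.height * image.width
    if size < min_fraction * n_pixels:
        raise NoTrapFoundError(
            f"largest component covers {size / n_pixels:.3f} of the frame, "
            f"below the minimum {min_fraction}"
        )

    roi_image = image.pixels * mask[..., None].astype(np.uint8)
    ys, xs = np.nonzero(mask)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return RoiMask(
        mask=mask,
        roi_image=roi_image,
        coverage_fraction=float(mask.sum() / n_pixels),
        polarity=polarity,
        threshold=t,
        bbox=bbox,
    )
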