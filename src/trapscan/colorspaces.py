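"""Pinned color-space conversions shared across the pipeline.

All conversions from 8-bit RGB are defined here in one place so that the
RoI extractor, the grayscale used for saliency, and the feature extractor
agree bit-for-bit:

* Luma / YCbCr: ITU-R BT.601 *full-range* (0-255 for all three planes,
  chroma offset 128).  This is the "digital" YCbCr used by JPEG, not the
  studio-swing variant.
* HSV: hue in degrees [0, 360), saturation and value in [0, 1].
* L*a*b*: CIE 1976, D65 illuminant, 2-degree observer (scikit-image
  defaults).

Integer planes are produced by rounding half-up; intermediate math is in
float64.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

# BT.601 luma weights (R, G, B)
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

# Full-range BT.601 RGB -> YCbCr matrix, rows = (Y, Cb, Cr)
YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])

COLOR_SPACES = ("RGB", "HSV", "YCbCr", "LAB")


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties away from zero-point-five going up.

    ``np.round`` rounds half to even, which makes pinned test values
    platform-stable but surprising; half-up matches the convention used
    throughout for producing 8-bit planes.
    """
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


def rgb_to_ycbcr_float(rgb: np.ndarray) -> np.ndarray:
    """RGB (any shape ending in 3, 0-255 scale) -> float YCbCr, full range."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of size 3, got shape {rgb.shape}")
    return rgb @ YCBCR_MATRIX.T + YCBCR_OFFSET


def rgb_to_ycbcr_u8(rgb: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit YCbCr planes (rounded half-up, clipped to [0, 255])."""
    ycc = rgb_to_ycbcr_float(rgb)
    return np.clip(round_half_up(ycc), 0, 255).astype(np.uint8)


def rgb_to_luma_u8(rgb: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit BT.601 luma plane."""
    y = np.asarray(rgb, dtype=np.float64) @ LUMA_WEIGHTS
    return np.clip(round_half_up(y), 0, 255).astype(np.uint8)


def rgb_to_hsv_float(rgb: np.ndarray) -> np.ndarray:
    """RGB (0-255) -> HSV with H in degrees [0, 360), S and V in [0, 1]."""
    rgb01 = np.asarray(rgb, dtype=np.float64) / 255.0
    hsv = _skcolor.rgb2hsv(rgb01.reshape(-1, 1, 3)).reshape(np.shape(rgb))
    hsv = hsv.copy()
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def rgb_to_lab_float(rgb: np.ndarray) -> np.ndarray:
    """RGB (0-255) -> CIE L*a*b* under D65."""
    rgb01 = np.asarray(rgb, dtype=np.float64) / 255.0
    return _skcolor.rgb2lab(rgb01.reshape(-1, 1, 3)).reshape(np.shape(rgb))


def hsv_to_rgb_u8(hsv: np.ndarray) -> np.ndarray:
    """HSV (H degrees, S/V in [0,1]) -> 8-bit RGB; inverse of rgb_to_hsv_float."""
    hsv = np.asarray(hsv, dtype=np.float64)
    shape = hsv.shape
    flat = hsv.reshape(-1, 1, 3).copy()
    flat[..., 0] = (flat[..., 0] % 360.0) / 360.0
    rgb01 = _skcolor.hsv2rgb(flat)
    out = np.clip(round_half_up(rgb01 * 255.0), 0, 255).astype(np.uint8)
    return out.reshape(shape)


def convert_pixels(pixels: np.ndarray, space: str) -> np.ndarray:
    """Convert an (n, 3) array of 8-bit RGB pixels into ``space``.

    Raises ``ValueError`` for an unknown space tag.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if space == "RGB":
        return pixels
    if space == "HSV":
        return rgb_to_hsv_float(pixels)
    if space == "YCbCr":
        return rgb_to_ycbcr_float(pixels)
    if space == "LAB":
        return rgb_to_lab_float(pixels)
    raise ValueError(f"unknown color space {space!r}; expected one of {COLOR_SPACES}")
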