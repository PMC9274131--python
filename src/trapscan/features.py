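"""Per-region mean-color feature vectors.

A segmented insect is only a handful of pixels with a ragged contour, so
shape descriptors are unreliable; color is the discriminative cue.  Each
region is reduced to the mean of its pixels' components in a chosen color
space — a 3-vector (f1, f2, f3) — computed over exactly the pixels under
the region mask (no bounding-box fill).  Four spaces are supported (RGB,
HSV, YCbCr, L*a*b*); HSV is the default for classification because the
separation between pale whiteflies, dark thrips and trap-yellow background
lives mostly in saturation and value, which brightness variation leaves
almost untouched.

Hue is an angle: the mean over pixels straddling the 0/360 wrap is taken
circularly (atan2 of the averaged sine/cosine).  A compatibility flag
restores the naive arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspaces import COLOR_SPACES, convert_pixels
from .regions import CandidateRegion
from .tiling import SubBlock

DEFAULT_SPACE = "HSV"


@dataclass
class FeatureVector:
    """Mean color of one region in one space."""

    values: tuple[float, float, float]
    space: str
    region_ref: int | str | None = None
    n_pixels: int = 1

    def __post_init__(self) -> None:
        if self.space not in COLOR_SPACES:
            raise ValueError(f"unknown color space {self.space!r}")
        if self.n_pixels < 1:
            raise ValueError("a feature vector needs at least one pixel")


def masked_object(block: SubBlock | np.ndarray, region: CandidateRegion) -> np.ndarray:
    """The (n, 3) RGB pixels of ``block`` under the region mask.

    The region is interpreted in the block's local coordinates (lift global
    regions back with :func:`trapscan.tiling.to_local` first).  Raises
    ``ValueError`` if the mask does not intersect the block.
    """
    pixels = getattr(block, "pixels", block)
    pixels = np.asarray(pixels)
    x0, y0, x1, y1 = region.bbox
    h, w = pixels.shape[:2]
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"region bbox {region.bbox} falls outside the {h}x{w} block")
    patch = pixels[y0:y1, x0:x1]
    out = patch[region.mask]
    if out.size == 0:
        raise ValueError("region mask does not cover any block pixel")
    return out


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Angular mean of angles in degrees, result in [0, 360)."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    mean = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())
    return float(np.rad2deg(mean) % 360.0)


def mean_color(
    pixels: np.ndarray,
    space: str = DEFAULT_SPACE,
    region_ref: int | str | None = None,
    circular_hue: bool = True,
) -> FeatureVector:
    """Average the pixels componentwise in the requested color space.

    ``pixels`` is an (n, 3) array of 8-bit RGB values.  With
    ``circular_hue`` (default) the H component of HSV is averaged on the
    circle; disabling it reproduces a plain arithmetic mean of hue.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.shape[1] != 3 or pixels.shape[0] < 1:
        raise ValueError("expected a non-empty (n, 3) pixel array")
    converted = convert_pixels(pixels, space)
    means = converted.mean(axis=0)
    if space == "HSV" and circular_hue:
        means = means.copy()
        means[0] = circular_mean_deg(converted[:, 0])
    return FeatureVector(
        values=(float(means[0]), float(means[1]), float(means[2])),
        space=space,
        region_ref=region_ref,
        n_pixels=int(pixels.shape[0]),
    )


def feature_table(
    block_regions: list[tuple[SubBlock | np.ndarray, CandidateRegion]],
    space: str = DEFAULT_SPACE,
    circular_hue: bool = True,
) -> tuple[np.ndarray, list[FeatureVector]]:
    """Stack region feature vectors into an (n, 3) matrix.

    Row order follows the input order (callers supply regions in global
    reading order); permuting the input permutes the rows identically.
    """
    vectors = []
    for i, (block, region) in enumerate(block_regions):
        pix = masked_object(block, region)
        vectors.append(mean_color(pix, space, region_ref=i, circular_hue=circular_hue))
    if not vectors:
        return np.empty((0, 3)), []
    matrix = np.array([v.values for v in vectors], dtype=np.float64)
    return matrix, vectors


#: chromatic component pair per space used by the separability diagnostic,
#: mirroring the classic scatter comparison: (R, G), (H, S), (Cb, Cr), (a*, b*)
DIAGNOSTIC_COMPONENTS = {"RGB": (0, 1), "HSV": (0, 1), "YCbCr": (1, 2), "LAB": (1, 2)}


def space_separability(
    features_by_space: dict[str, np.ndarray],
    labels: np.ndarray,
    components: dict[str, tuple[int, int]] | None = None,
) -> dict[str, float]:
    """Silhouette score of the class clustering in each color space.

    The comparison is made on the two components classically scattered
    against each other for this task — (R, G), (H, S), (Cb, Cr) and
    (a*, b*) — z-scored per component so spaces with heterogeneous ranges
    (hue in degrees vs saturation in [0, 1]) meet on an equal footing.
    Higher means better separated; pass ``components=None`` entries or a
    custom mapping to diagnose other projections.
    """
    from sklearn.metrics import silhouette_score

    components = DIAGNOSTIC_COMPONENTS if components is None else components
    labels = np.asarray(labels)
    scores = {}
    for space, mat in features_by_space.items():
        mat = np.asarray(mat, dtype=np.float64)
        cols = components.get(space)
        if cols is not None:
            mat = mat[:, list(cols)]
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        z = (mat - mat.mean(axis=0)) / sd
        scores[space] = float(silhouette_score(z, labels))
    return scores
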