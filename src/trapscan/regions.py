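"""From saliency map to candidate insect regions.

The saliency histogram of a trap block is single-peaked with the peak at
the dark end: almost every pixel is redundant background, and the few
salient pixels form a long bright tail.  The triangle method suits exactly
this shape — draw a line from the histogram peak to the far end of the
bright tail and threshold at the bin farthest (perpendicularly) from that
line, i.e. at the elbow of the decay.

Foreground components may still contain several touching insects, so each
is split by a watershed on the inverted saliency relief, seeded from its
regional maxima (with close maxima merged).  Finally, components whose
pixel area falls outside the plausible insect range are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .saliency import SaliencyMap


class DegenerateHistogramError(ValueError):
    """Raised when a map has no contrast to threshold."""


@dataclass
class CandidateRegion:
    """One segmented connected component.

    ``bbox`` is (x0, y0, x1, y1), half-open, in global coordinates once the
    region has been lifted out of its block; ``mask`` covers exactly the
    bbox.  ``area`` is the true-pixel count of the mask.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int
    centroid: tuple[float, float]  # (x, y)
    block_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area != int(self.mask.sum()):
            raise ValueError("area must equal the number of true mask pixels")
        if self.area < 1:
            raise ValueError("region must contain at least one pixel")
        x0, y0, x1, y1 = self.bbox
        if self.mask.shape != (y1 - y0, x1 - x0):
            raise ValueError("mask shape must match bbox extent")


def region_from_mask(
    mask: np.ndarray, origin: tuple[int, int] = (0, 0), block_offset: tuple[int, int] = (0, 0)
) -> CandidateRegion:
    """Build a CandidateRegion from a full-frame boolean mask.

    ``origin`` is the (x, y) of the mask array's top-left corner.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    tight = mask[y0:y1, x0:x1]
    ox, oy = origin
    return CandidateRegion(
        mask=tight,
        bbox=(x0 + ox, y0 + oy, x1 + ox, y1 + oy),
        area=int(tight.sum()),
        centroid=(float(xs.mean() + ox), float(ys.mean() + oy)),
        block_offset=block_offset,
    )


def triangle_bin(counts: np.ndarray) -> int:
    """Triangle-method threshold bin of a histogram.

    The anchor line runs from the peak bin (ties toward the darker bin) to
    the farthest non-empty bin on the bright side of the peak.  Axes are
    normalized — bin index and count each mapped to [0, 1] — so the result
    does not depend on image size or histogram scale.  Returns the bin with
    the maximum perpendicular distance to the line (ties toward the lowest
    bin).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise DegenerateHistogramError("histogram must be 1-D with >= 2 bins")
    if counts.sum() <= 0:
        raise DegenerateHistogramError("empty histogram")
    peak = int(np.argmax(counts))
    nonzero = np.nonzero(counts)[0]
    end = int(nonzero.max())
    if end <= peak:
        raise DegenerateHistogramError(
            "no bright tail beyond the peak; map is flat or inverted"
        )
    n = counts.size
    x = np.arange(n, dtype=np.float64) / (n - 1)
    y = counts / counts.max()
    # perpendicular distance of (x_b, y_b) to the line through peak and end
    dx, dy = x[end] - x[peak], y[end] - y[peak]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[peak]) - dx * (y - y[peak])) / norm
    bins = np.arange(peak, end + 1)
    best = bins[np.argmax(dist[peak : end + 1])]  # argmax ties -> lowest bin
    return int(best)


def triangle_threshold(
    saliency: SaliencyMap | np.ndarray,
    bins: int = 256,
    max_peak_fraction: float | None = 0.125,
) -> float:
    """Adaptive threshold of a saliency map via the triangle method.

    The map (normalized to [0, 1]) is histogrammed into ``bins`` equal bins
    over [0, 1] and the triangle bin's upper edge is returned, so that
    ``value > threshold`` selects the bright side of the elbow.

    The geometry presumes a histogram peaked close to the dark end: true
    exactly when the block holds genuine novelty against a redundant
    background.  A block of pure noise normalizes to a mid-peaked histogram
    instead; when the peak falls beyond ``max_peak_fraction`` of the axis
    the map is rejected as containing no salient object (pass None to skip
    the check).
    """
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if values.size == 0:
        raise DegenerateHistogramError("empty saliency map")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    if max_peak_fraction is not None:
        peak = int(np.argmax(counts))
        if peak > max_peak_fraction * (bins - 1):
            raise DegenerateHistogramError(
                f"histogram peak at bin {peak}/{bins} is not near the dark end; "
                "block contains no salient novelty"
            )
    b = triangle_bin(counts)
    return float(edges[b + 1])


def binarize(saliency: SaliencyMap | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean foreground mask: saliency strictly above the threshold."""
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    return values > threshold


def watershed_split(
    binary: np.ndarray,
    saliency: SaliencyMap | np.ndarray,
    min_peak_separation: int = 3,
) -> list[CandidateRegion]:
    """Split foreground components along watershed lines of the saliency relief.

    Markers are the regional maxima of the saliency map inside the
    foreground, with maxima closer than ``min_peak_separation`` px merged;
    a component that yields no marker (a perfectly flat plateau) is kept
    whole.  The returned region masks partition the foreground exactly.
    """
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    offset = saliency.block_offset if isinstance(saliency, SaliencyMap) else (0, 0)
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return []

    comp_labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    peaks = peak_local_max(
        values,
        min_distance=min_peak_separation,
        labels=comp_labels,
        exclude_border=False,
    )
    markers = np.zeros(values.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i

    labels = watershed(-values, markers=markers, mask=binary)
    # components with no marker drown entirely; pass them through unchanged
    missed = np.unique(comp_labels[(labels == 0) & binary])
    next_label = int(labels.max()) + 1
    for comp in missed:
        labels[(comp_labels == comp) & (labels == 0)] = next_label
        next_label += 1

    regions = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        regions.append(region_from_mask(labels == lab, block_offset=offset))
    # stable reading order: by (y0, x0)
    regions.sort(key=lambda r: (r.bbox[1], r.bbox[0]))
    return regions


def refine_regions(
    regions: list[CandidateRegion],
    saliency: SaliencyMap | np.ndarray,
    level: float = 0.5,
) -> list[CandidateRegion]:
    """Shrink each region to the half-maximum support of its saliency peak.

    The elbow threshold that *detects* a region necessarily sits at the
    foot of the background lobe, so the binary blob includes the blur skirt
    around each object and overstates its size severalfold.  The level set
    at ``level`` x the region's own peak saliency tracks the object
    boundary instead (for a blurred compact object the half-maximum
    contour sits at the original edge), so areas measured on the refined
    support are comparable with true object sizes.  If the level set falls
    apart, the largest connected piece is kept.
    """
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    out = []
    for r in regions:
        x0, y0, x1, y1 = r.bbox
        sub = np.where(r.mask, values[y0:y1, x0:x1], -np.inf)
        keep = sub >= level * sub.max()
        lab, n = ndimage.label(keep, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            keep = lab == (int(np.argmax(sizes)) + 1)
        out.append(region_from_mask(keep, origin=(x0, y0), block_offset=r.block_offset))
    return out


def size_filter(
    regions: list[CandidateRegion], min_px: int = 5, max_px: int = 25
) -> list[CandidateRegion]:
    """Keep regions whose pixel area lies in [min_px, max_px], inclusive."""
    return [r for r in regions if min_px <= r.area <= max_px]


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major, starts with a 0-run)."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    # boundaries between runs
    changes = np.nonzero(np.diff(flat))[0] + 1
    lengths = np.diff(np.concatenate([[0], changes, [flat.size]]))
    counts = lengths.tolist()
    if flat.size and flat[0]:
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": [int(c) for c in counts]}


def rle_to_mask(rle: dict) -> np.ndarray:
    """Inverse of :func:`mask_to_rle`."""
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    value = False
    for run in rle["counts"]:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(h, w)
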