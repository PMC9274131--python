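"""Sliding-window tiling of the RoI into fixed-size sub-blocks.

Small insects are far easier to pick out at block scale than against the
whole card, so the RoI bounding box is tiled into (by default) 64 x 64
blocks.  Right/bottom remainders are zero-padded to full block size —
padding with zeros keeps the padded area non-salient after the residual
transform's mean removal.  Each block carries its global offset so that
regions found inside it can be lifted back to image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .regions import CandidateRegion
from .roi import RoiMask


@dataclass
class SubBlock:
    """One tile of the RoI image with its global placement."""

    pixels: np.ndarray  # (block, block, 3) uint8, zero-padded if at an edge
    offset_x: int
    offset_y: int
    inside_roi_fraction: float
    valid_mask: np.ndarray | None = None  # true where the tile overlaps the RoI mask


def split_blocks(
    roi: RoiMask, block: int = 64, stride: int = 64
) -> list[SubBlock]:
    """Tile the RoI bounding box into row-major ``block``-sized sub-blocks.

    Blocks that do not intersect the RoI mask at all are dropped.  With the
    default ``stride == block`` the tiling is a partition; a smaller stride
    gives overlapping blocks (each RoI pixel then appears in at least one
    block).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if block < 8:
        raise ValueError("block size must be >= 8")
    if not roi.mask.any():
        return []
    x0, y0, x1, y1 = roi.bbox
    h, w = roi.mask.shape
    blocks: list[SubBlock] = []
    for top in range(y0, y1, stride):
        for left in range(x0, x1, stride):
            tile = np.zeros((block, block, 3), dtype=np.uint8)
            tile_mask = np.zeros((block, block), dtype=bool)
            b = min(top + block, h)
            r = min(left + block, w)
            if b > top and r > left:
                tile[: b - top, : r - left] = roi.roi_image[top:b, left:r]
                tile_mask[: b - top, : r - left] = roi.mask[top:b, left:r]
            frac = float(tile_mask.mean())
            if frac == 0.0:
                continue
            blocks.append(
                SubBlock(
                    pixels=tile,
                    offset_x=left,
                    offset_y=top,
                    inside_roi_fraction=frac,
                    valid_mask=tile_mask,
                )
            )
    return blocks


def to_global(region: CandidateRegion, block: SubBlock) -> CandidateRegion:
    """Shift a block-local region into global image coordinates."""
    x0, y0, x1, y1 = region.bbox
    dx, dy = block.offset_x, block.offset_y
    cx, cy = region.centroid
    return replace(
        region,
        bbox=(x0 + dx, y0 + dy, x1 + dx, y1 + dy),
        centroid=(cx + dx, cy + dy),
        block_offset=(dx, dy),
    )


def to_local(region: CandidateRegion, block: SubBlock) -> CandidateRegion:
    """Inverse of :func:`to_global`."""
    x0, y0, x1, y1 = region.bbox
    dx, dy = block.offset_x, block.offset_y
    cx, cy = region.centroid
    return replace(
        region,
        bbox=(x0 - dx, y0 - dy, x1 - dx, y1 - dy),
        centroid=(cx - dx, cy - dy),
        block_offset=(0, 0),
    )
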