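import numpy as np
import pytest

from trapscan.regions import (
    CandidateRegion,
    DegenerateHistogramError,
    binarize,
    refine_regions,
    size_filter,
    triangle_bin,
    triangle_threshold,
    watershed_split,
)
from trapscan.saliency import spectral_residual

from .conftest import planted_gray_block
from .oracles import exhaustive_triangle_bin, random_unimodal_histogram


class TestTriangle:
    def test_two_point_histogram_threshold_between_endpoints(self):
        counts = np.zeros(256)
        counts[0] = 100
        counts[255] = 1
        assert 0 < triangle_bin(counts) < 255

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            counts = random_unimodal_histogram(rng)
            assert triangle_bin(counts) == exhaustive_triangle_bin(counts)

    def test_exponential_decay_with_flat_tail(self):
        b = np.arange(256, dtype=float)
        counts = np.round(1000 * np.exp(-b / 10)) + 1
        assert triangle_bin(counts) == exhaustive_triangle_bin(counts)

    def test_count_scaling_invariance(self):
        rng = np.random.default_rng(3)
        counts = random_unimodal_histogram(rng)
        assert triangle_bin(counts) == triangle_bin(counts * 10)

    def test_constant_map_rejected(self):
        sal = spectral_residual(np.full((64, 64), 77.0))
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(sal)

    def test_empty_map_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(np.empty((0,)))

    def test_mid_peaked_histogram_rejected_as_noise(self):
        """The method presumes a dark-end peak; noise maps violate it."""
        rng = np.random.default_rng(0)
        noise_map = rng.uniform(0.3, 0.7, (64, 64))
        with pytest.raises(DegenerateHistogramError, match="novelty"):
            triangle_threshold(noise_map)


class TestBinarize:
    def test_threshold_extremes(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (16, 16))
        assert not binarize(values, values.max()).any()
        assert binarize(values, values.min() - 1e-9).all()

    def test_planted_blob_map_segments_blob(self):
        rng = np.random.default_rng(4)
        block, truths = planted_gray_block(rng, n_blobs=1)
        sal = spectral_residual(block)
        binary = binarize(sal, triangle_threshold(sal))
        cx, cy, _ = truths[0]
        assert binary[int(cy), int(cx)]
        assert (~binary).mean() >= 0.95


class TestWatershed:
    def test_disjoint_blobs_equal_connected_components(self):
        binary = np.zeros((64, 64), dtype=bool)
        binary[10:14, 10:14] = True
        binary[40:45, 40:44] = True
        relief = np.zeros((64, 64))
        relief[11, 11] = 1.0
        relief[42, 42] = 1.0
        regions = watershed_split(binary, relief)
        assert len(regions) == 2
        assert sorted(r.area for r in regions) == [16, 20]

    def test_single_convex_blob_passes_through(self):
        binary = np.zeros((32, 32), dtype=bool)
        binary[8:14, 8:13] = True
        relief = np.zeros((32, 32))
        relief[10, 10] = 1.0
        regions = watershed_split(binary, relief)
        assert len(regions) == 1
        assert regions[0].area == 30

    def test_touching_gaussians_split_near_true_peaks(self):
        yy, xx = np.mgrid[0:64, 0:64]
        peaks = [(30.0, 26.0), (30.0, 36.0)]
        relief = sum(
            np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * 3.0**2)) for py, px in peaks
        )
        binary = relief > 0.2
        regions = watershed_split(binary, relief, min_peak_separation=3)
        assert len(regions) == 2
        got = sorted(r.centroid for r in regions)
        for (cx, cy), (py, px) in zip(got, peaks):
            assert np.hypot(cx - px, cy - py) <= 3.0

    def test_partition_property_on_random_binaries(self):
        """Masks are disjoint and union exactly the foreground."""
        rng = np.random.default_rng(23)
        from scipy import ndimage

        for _ in range(100):
            blob_seed = rng.uniform(0, 1, (32, 32))
            relief = ndimage.gaussian_filter(blob_seed, 2.0)
            binary = relief > np.percentile(relief, 75)
            regions = watershed_split(binary, relief)
            canvas = np.zeros((32, 32), dtype=int)
            for r in regions:
                x0, y0, x1, y1 = r.bbox
                canvas[y0:y1, x0:x1] += r.mask
            assert canvas.max() <= 1  # disjoint
            assert np.array_equal(canvas > 0, binary)  # union = foreground

    def test_empty_binary_gives_no_regions(self):
        assert watershed_split(np.zeros((8, 8), dtype=bool), np.zeros((8, 8))) == []


class TestSizeFilter:
    def test_bounds_are_inclusive_on_worked_area_set(self):
        regions = []
        for area in (3, 5, 17, 25, 26):
            side = 1
            mask = np.zeros((1, area), dtype=bool)
            mask[0, :area] = True
            regions.append(
                CandidateRegion(
                    mask=mask, bbox=(0, 0, area, 1), area=area, centroid=(0, 0)
                )
            )
        kept = size_filter(regions, 5, 25)
        assert [r.area for r in kept] == [5, 17, 25]

    def test_empty_input(self):
        assert size_filter([]) == []

    def test_unbounded_filter_is_identity(self):
        mask = np.ones((2, 2), dtype=bool)
        regions = [CandidateRegion(mask=mask, bbox=(0, 0, 2, 2), area=4, centroid=(0.5, 0.5))]
        assert [id(r) for r in size_filter(regions, 1, 10**9)] == [id(r) for r in regions]

    def test_monotone_in_bounds(self):
        rng = np.random.default_rng(5)
        regions = []
        for _ in range(30):
            a = int(rng.integers(1, 40))
            mask = np.zeros((1, a), dtype=bool)
            mask[0, :] = True
            regions.append(CandidateRegion(mask=mask, bbox=(0, 0, a, 1), area=a, centroid=(0, 0)))
        narrow = {id(r) for r in size_filter(regions, 5, 25)}
        wide = {id(r) for r in size_filter(regions, 3, 30)}
        assert narrow <= wide


class TestRefine:
    def test_refined_mask_is_subset_and_smaller(self):
        rng = np.random.default_rng(2)
        block, _ = planted_gray_block(rng, n_blobs=2)
        sal = spectral_residual(block)
        regions = watershed_split(binarize(sal, triangle_threshold(sal)), sal)
        refined = refine_regions(regions, sal, level=0.5)
        for raw, ref in zip(regions, refined):
            assert ref.area <= raw.area
            rx0, ry0, _, _ = raw.bbox
            fx0, fy0, fx1, fy1 = ref.bbox
            sub = np.zeros_like(raw.mask)
            sub[fy0 - ry0 : fy1 - ry0, fx0 - rx0 : fx1 - rx0] = ref.mask
            assert np.all(raw.mask | ~sub)  # subset

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            refine_regions([], np.zeros((4, 4)), level=1.5)


def test_end_to_end_proposal_recall_on_planted_blocks():
    """>= 95% of 8-20 px blobs produce a centroid within 3 px of truth."""
    rng = np.random.default_rng(0)
    hits = total = 0
    for _ in range(100):
        block, truths = planted_gray_block(rng, n_blobs=10)
        sal = spectral_residual(block)
        try:
            thr = triangle_threshold(sal)
        except DegenerateHistogramError:
            total += len(truths)
            continue
        regions = size_filter(
            refine_regions(watershed_split(binarize(sal, thr), sal), sal)
        )
        total += len(truths)
        used = set()
        for cx, cy, _ in truths:
            for i, r in enumerate(regions):
                if i not in used and np.hypot(r.centroid[0] - cx, r.centroid[1] - cy) <= 3:
                    used.add(i)
                    hits += 1
                    break
    assert hits / total >= 0.95


class TestRleSerialization:
    def test_round_trip_random_masks(self):
        from trapscan.regions import mask_to_rle, rle_to_mask

        rng = np.random.default_rng(13)
        for _ in range(20):
            mask = rng.uniform(0, 1, (9, 13)) > rng.uniform(0.2, 0.8)
            assert np.array_equal(rle_to_mask(mask_to_rle(mask)), mask)

    def test_all_true_and_all_false(self):
        from trapscan.regions import mask_to_rle, rle_to_mask

        for mask in (np.ones((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool)):
            assert np.array_equal(rle_to_mask(mask_to_rle(mask)), mask)
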