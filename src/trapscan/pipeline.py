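"""End-to-end orchestration: RoI -> tiling -> saliency -> regions ->
features -> classification, plus training-from-crops and benchmarking.

The pipeline is configured by a single :class:`PipelineConfig` that
round-trips through YAML and hashes stably, so a run directory can record
exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import ClassifierModel, LabeledSample, SVMConfig, predict, train
from .evaluation import Detection, DetectionSet, GroundTruth, evaluate_images
from .features import feature_table, masked_object, mean_color
from .regions import (
    CandidateRegion,
    DegenerateHistogramError,
    binarize,
    refine_regions,
    size_filter,
    triangle_threshold,
    watershed_split,
)
from .roi import DegenerateHistogramError as RoiDegenerateError
from .roi import NoTrapFoundError, RoiMask, TrapImage, extract_roi
from .saliency import SaliencyParams, block_to_gray, spectral_residual
from .synth import SceneSpec, generate_scene, generate_training_set
from .tiling import SubBlock, split_blocks, to_global


@dataclass
class PipelineConfig:
    """Every tunable of the detection pipeline in one serializable bag."""

    block_size: int = 64
    #: half-block overlap: an insect straddling a block border is whole in
    #: the neighbouring block, and duplicate finds are merged downstream
    stride: int = 32
    saliency: SaliencyParams = field(default_factory=SaliencyParams)
    triangle_bins: int = 256
    min_peak_separation: int = 4
    refine_level: float = 0.5
    feature_core_level: float = 0.7  # stricter level set used for color features
    dedupe_min_sep: float = 6.0  # 0 disables duplicate-fragment merging
    min_area: int = 5
    max_area: int = 25
    color_space: str = "HSV"
    match_dist: float = 8.0
    roi_min_fraction: float = 0.05
    dedupe_seams: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "saliency" in d and isinstance(d["saliency"], dict):
            d["saliency"] = SaliencyParams(**d["saliency"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: PipelineConfig) -> dict:
    """Machine-readable record of what produced a run."""
    return {
        "trapscan_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "seed": config.seed,
    }


@dataclass
class Proposal:
    """One candidate region with every view the later stages need.

    ``local``/``globl`` are the half-maximum (sizing) region in block and
    image coordinates; ``core`` is the stricter level set used for color
    features — boundary pixels of a 10 px animal are card-insect mixtures,
    and averaging them drags every class toward the card color.
    """

    block: SubBlock
    local: CandidateRegion
    globl: CandidateRegion
    core: CandidateRegion


def propose_regions(roi: RoiMask, config: PipelineConfig) -> list[Proposal]:
    """Candidate insect regions of one RoI.

    Per block: saliency map, triangle threshold, watershed split,
    half-maximum refinement, then the plausible-size filter.  Blocks with a
    flat map or a histogram that is not dark-peaked (no novelty) contribute
    nothing; foreground in the zero-padded remainder area is clipped to the
    RoI before any area is measured.
    """
    proposals = []
    for block in split_blocks(roi, block=config.block_size, stride=config.stride):
        gray = block_to_gray(block)
        sal = spectral_residual(
            gray, config.saliency, block_offset=(block.offset_x, block.offset_y)
        )
        if sal.values.max() <= 0:
            continue
        try:
            thr = triangle_threshold(sal, bins=config.triangle_bins)
        except DegenerateHistogramError:
            continue
        binary = binarize(sal, thr)
        if block.valid_mask is not None:
            binary &= block.valid_mask
        if not binary.any():
            continue
        regions = watershed_split(binary, sal, min_peak_separation=config.min_peak_separation)
        regions = refine_regions(regions, sal, level=config.refine_level)
        regions = size_filter(regions, min_px=config.min_area, max_px=config.max_area)
        cores = refine_regions(regions, sal, level=config.feature_core_level)
        for region, core in zip(regions, cores):
            proposals.append(
                Proposal(block=block, local=region, globl=to_global(region, block), core=core)
            )
    return proposals


def _dedupe(
    detections: list[Detection],
    areas: list[int] | None = None,
    min_sep: float = 4.0,
) -> list[Detection]:
    """Merge detections whose centers nearly coincide, keeping the largest.

    One animal occasionally yields two fragments — split by a watershed
    ridge, or found in two blocks when the stride overlaps — and a
    double-counted insect distorts the population estimate more than a
    slightly wrong boundary does.
    """
    if areas is None:
        areas = [0] * len(detections)
    order = sorted(range(len(detections)), key=lambda i: -areas[i])
    kept_idx: list[int] = []
    for i in order:
        cx, cy = detections[i].center()
        if any(
            np.hypot(cx - detections[j].center()[0], cy - detections[j].center()[1]) < min_sep
            for j in kept_idx
        ):
            continue
        kept_idx.append(i)
    return [detections[i] for i in sorted(kept_idx)]


def detect_image(
    image: TrapImage,
    model: ClassifierModel,
    config: PipelineConfig | None = None,
    image_id: str = "",
) -> tuple[DetectionSet, dict]:
    """Run the full pipeline on one photograph.

    Returns the classified detections (including background-labeled
    regions) and a stats dict with per-stage counts.  A frame without a
    recognizable card yields an empty detection set.
    """
    config = config or PipelineConfig()
    stats = {"config_hash": config.hash()}
    try:
        roi = extract_roi(image, min_fraction=config.roi_min_fraction)
    except (NoTrapFoundError, RoiDegenerateError):
        stats.update({"roi_found": False, "n_candidates": 0})
        return DetectionSet(detections=[], image_id=image_id), stats
    stats["roi_found"] = True
    stats["roi_coverage"] = roi.coverage_fraction

    proposals = propose_regions(roi, config)
    stats["n_candidates"] = len(proposals)
    if not proposals:
        return DetectionSet(detections=[], image_id=image_id), stats

    matrix, _ = feature_table(
        [(p.block, p.core) for p in proposals], space=config.color_space
    )
    labels = predict(model, matrix)
    detections = [
        Detection(
            bbox=p.globl.bbox,
            label=str(lab),
            centroid=p.globl.centroid,
            region_ref=i,
        )
        for i, (p, lab) in enumerate(zip(proposals, labels))
    ]
    if config.dedupe_min_sep > 0 or config.dedupe_seams or config.stride < config.block_size:
        areas = [proposals[d.region_ref].globl.area for d in detections]
        detections = _dedupe(detections, areas, min_sep=max(config.dedupe_min_sep, 1.0))
    ds = DetectionSet(detections=detections, image_id=image_id)
    stats["counts"] = ds.counts
    return ds, stats


def crop_feature(crop: np.ndarray, config: PipelineConfig | None = None):
    """Mean-color feature vector of a training crop.

    The crop goes through the same saliency + segmentation steps as a
    detection block, the region closest to the crop center is chosen, and
    its feature-core pixels are averaged; a crop with no segmentable object
    (a clean background patch) falls back to a small central disk so its
    feature describes the card surface.
    """
    config = config or PipelineConfig()
    crop = np.asarray(crop)
    h, w = crop.shape[:2]
    gray = block_to_gray(crop)
    region_pixels = None
    try:
        sal = spectral_residual(gray, config.saliency)
        thr = triangle_threshold(sal, bins=config.triangle_bins)
        regions = watershed_split(
            binarize(sal, thr), sal, min_peak_separation=config.min_peak_separation
        )
        regions = refine_regions(regions, sal, level=config.refine_level)
        regions = size_filter(regions, min_px=config.min_area, max_px=config.max_area)
        if regions:
            cx0, cy0 = w / 2, h / 2
            best_i = int(
                np.argmin(
                    [np.hypot(r.centroid[0] - cx0, r.centroid[1] - cy0) for r in regions]
                )
            )
            core = refine_regions(
                [regions[best_i]], sal, level=config.feature_core_level
            )[0]
            x0, y0, x1, y1 = core.bbox
            region_pixels = crop[y0:y1, x0:x1][core.mask]
    except (ValueError, DegenerateHistogramError):
        pass
    if region_pixels is None:
        yy, xx = np.mgrid[0:h, 0:w]
        disk = np.hypot(xx - w / 2, yy - h / 2) <= 2.5
        region_pixels = crop[disk]
    fv = mean_color(region_pixels, space=config.color_space)
    return fv


def train_from_crops(
    crops: list[np.ndarray],
    labels: list[str],
    config: PipelineConfig | None = None,
    svm: SVMConfig | None = None,
) -> ClassifierModel:
    """Extract crop features and fit the classifier."""
    config = config or PipelineConfig()
    samples = []
    for crop, label in zip(crops, labels):
        fv = crop_feature(crop, config)
        samples.append(LabeledSample(features=fv, label=label))
    return train(samples, config=svm, seed=config.seed, space=config.color_space)


def harvest_background_samples(
    config: PipelineConfig | None = None,
    n_scenes: int = 12,
    per_scene_cap: int = 40,
    seed: int = 0,
    spec: SceneSpec | None = None,
    noise_boost: float = 3.0,
) -> list[LabeledSample]:
    """Background-class features from insect-free degraded scenes.

    The background category has to represent what the proposal stage
    actually produces on a trap with no insects: glue spots, smear edges,
    stripe fragments and plain-card noise specks.  Rendering insect-free
    scenes and pushing them through the proposal pipeline samples exactly
    that population (the field-data analogue is cropping detected
    non-target objects).  Plain card-colored proposals vastly outnumber the
    artifact-colored ones, so only ``per_scene_cap`` of them are kept per
    scene while every artifact-colored proposal (saturation below 0.85) is
    retained; the harvest scenes' noise rates are additionally multiplied
    by ``noise_boost`` so rare artifact types (stripes, smears) contribute
    enough samples for the classifier to learn their color range.
    """
    config = config or PipelineConfig()
    base = spec or SceneSpec()
    rng = np.random.default_rng([seed, 9])
    samples: list[LabeledSample] = []
    for _ in range(n_scenes):
        scene = replace(
            base,
            n_whitefly=0,
            n_thrips=0,
            noise=base.noise.scaled(noise_boost),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, _ = generate_scene(scene)
        try:
            roi = extract_roi(image, min_fraction=config.roi_min_fraction)
        except NoTrapFoundError:
            continue
        feats = [
            mean_color(masked_object(p.block, p.core), space=config.color_space)
            for p in propose_regions(roi, config)
        ]
        if config.color_space == "HSV":
            rare = [f for f in feats if f.values[1] < 0.85]
            common = [f for f in feats if f.values[1] >= 0.85]
        else:
            rare, common = [], feats
        take = rare + common[:per_scene_cap]
        samples.extend(LabeledSample(features=f, label="background") for f in take)
    return samples


def train_synthetic_model(
    n_per_class: int = 500,
    config: PipelineConfig | None = None,
    svm: SVMConfig | None = None,
    seed: int = 0,
    spec: SceneSpec | None = None,
) -> ClassifierModel:
    """Render a labeled training set and fit the classifier.

    Whitefly and thrips samples come from ``n_per_class`` rendered 32x32
    crops each; the background class is harvested from insect-free scenes
    (see :func:`harvest_background_samples`) so it covers the artifact
    population the detector will actually face.
    """
    config = config or PipelineConfig()
    crops, labels = generate_training_set(n_per_class, seed=seed, spec=spec)
    samples = []
    for crop, label in zip(crops, labels):
        if label == "background":
            continue
        samples.append(LabeledSample(features=crop_feature(crop, config), label=label))
    samples.extend(
        harvest_background_samples(config, seed=seed, spec=spec)
    )
    return train(samples, config=svm, seed=config.seed, space=config.color_space)


def run_benchmark(
    model: ClassifierModel,
    n_images: int = 18,
    config: PipelineConfig | None = None,
    seed: int = 0,
    base_spec: SceneSpec | None = None,
    count_range: tuple[int, int] = (4, 24),
) -> dict:
    """Detect on a batch of synthetic scenes and score against ground truth.

    Per-image insect counts are drawn uniformly from ``count_range`` so the
    automatic-vs-manual count regression has spread.  Returns the
    :func:`trapscan.evaluation.evaluate_images` report.
    """
    config = config or PipelineConfig()
    base_spec = base_spec or SceneSpec()
    rng = np.random.default_rng([seed, 3])
    detection_sets, truths = [], []
    for i in range(n_images):
        spec = replace(
            base_spec,
            n_whitefly=int(rng.integers(count_range[0], count_range[1] + 1)),
            n_thrips=int(rng.integers(count_range[0], count_range[1] + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, ann = generate_scene(spec)
        image_id = f"scene_{i:03d}"
        ds, _ = detect_image(image, model, config, image_id=image_id)
        detection_sets.append(ds)
        truths.append(
            GroundTruth(
                points=[(r.x, r.y, r.label) for r in ann.itertuples()], image_id=image_id
            )
        )
    return evaluate_images(
        detection_sets, truths, max_dist=config.match_dist
    )
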