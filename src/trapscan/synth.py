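"""Synthetic sticky-trap scenes with exact ground truth.

Real greenhouse trap photographs are not redistributable, so every stage
of the pipeline is exercised against rendered scenes instead: a bright
yellow card on a dark background, sprinkled with small elliptical insects
— pale, low-saturation "whiteflies" and dark yellow-brown "thrips" — plus
the degradations a trap actually suffers: glue spots, stripes and bulk
smears, an illumination gradient, optional specular reflection, and sensor
noise.

Class color models are HSV mean/sd triples.  The defaults are synthetic
stand-ins chosen to reproduce the qualitative color-space behaviour of the
real classes (brightness variation smears the clusters in RGB while the
separation survives in saturation/value), not measured field values.
Insect shape is a deliberately minimal model — random-orientation ellipses
with eccentricity in [1, 2.5] — because shape is not a cue the classifier
uses.

Everything is deterministic given the spec's seed; insect layout and noise
draw from independent substreams, so scaling the noise leaves the layout
(and hence the annotations) bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .colorspaces import hsv_to_rgb_u8
from .roi import TrapImage

TRAP_HSV = (55.0, 0.92, 0.88)  # card yellow (nominal)
#: per-frame card color spread: cards age and yellow differently between
#: frames, so the card hue/chroma is drawn once per scene and per crop
TRAP_HSV_SD = (6.0, 0.025, 0.02)
OUTSIDE_RGB = (45, 45, 50)  # scene behind the card
SENSOR_NOISE_SD = 2.0

#: HSV (mean, sd) per class; hue in degrees, S and V in [0, 1]
WHITEFLY_COLOR = ((60.0, 0.12, 0.96), (8.0, 0.035, 0.025))
THRIPS_COLOR = ((32.0, 0.72, 0.35), (6.0, 0.06, 0.05))
GLUE_SPOT_COLOR = ((58.0, 0.45, 0.97), (12.0, 0.05, 0.02))

#: per-insect multiplicative brightness jitter (uneven lighting on the card)
BRIGHTNESS_JITTER_SD = 0.06

#: across-image illumination variation: training crops are drawn from many
#: frames taken over days and times of day, so each crop carries its own
#: exposure gain (and its own card color draw).  A rendered scene is one
#: frame from one deployment: its exposure is the nominal 1.0 unless the
#: spec overrides it.  The clip is asymmetric because auto-exposure
#: prevents gross overexposure, and the bright cap keeps the pale classes
#: inside 8-bit range.
CROP_GAIN_SD = 0.10
CROP_GAIN_CLIP = (0.65, 1.12)


def _crop_gain(rng: np.random.Generator) -> float:
    """Per-crop exposure gain."""
    return float(np.clip(1.0 + CROP_GAIN_SD * rng.normal(), *CROP_GAIN_CLIP))


class PlacementError(RuntimeError):
    """Raised when insects cannot be placed without overlap."""


@dataclass
class NoiseSpec:
    """Degradation layers of one scene.

    spot_density:
        Glue spots per 10^4 card pixels (drawn over insects — old glue
        creeps across trapped animals).
    stripe_count / bulk_blob_count:
        Elongated smears and large whitened patches, drawn under insects.
    illumination_gradient:
        Maximum fractional brightness change corner-to-corner.
    reflection_patch:
        Optional ((x0, y0, x1, y1), gain) specular highlight.
    """

    spot_density: float = 0.4
    stripe_count: int = 1
    bulk_blob_count: int = 1
    illumination_gradient: float = 0.10
    reflection_patch: tuple[tuple[int, int, int, int], float] | None = None

    def __post_init__(self) -> None:
        if min(self.spot_density, self.stripe_count, self.bulk_blob_count) < 0:
            raise ValueError("noise rates must be >= 0")
        if self.illumination_gradient < 0:
            raise ValueError("illumination_gradient must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        """Scale every degradation jointly by ``factor`` (1.0 = identity)."""
        patch = self.reflection_patch
        if patch is not None:
            bbox, gain = patch
            patch = (bbox, 1.0 + (gain - 1.0) * factor)
        return NoiseSpec(
            spot_density=self.spot_density * factor,
            stripe_count=int(round(self.stripe_count * factor)),
            bulk_blob_count=int(round(self.bulk_blob_count * factor)),
            illumination_gradient=self.illumination_gradient * factor,
            reflection_patch=patch,
        )


@dataclass
class SceneSpec:
    """Full description of one synthetic trap photograph."""

    width: int = 640
    height: int = 480
    trap_bbox: tuple[int, int, int, int] | None = None  # default: 10% inset
    n_whitefly: int = 12
    n_thrips: int = 12
    whitefly_color_model: tuple = WHITEFLY_COLOR
    thrips_color_model: tuple = THRIPS_COLOR
    insect_area_range: tuple[float, float] = (8.0, 20.0)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    #: optional fixed exposure gain for the whole frame (None = nominal 1.0)
    illumination_gain: float | None = None

    def resolved_trap_bbox(self) -> tuple[int, int, int, int]:
        if self.trap_bbox is not None:
            return self.trap_bbox
        mx, my = int(self.width * 0.1), int(self.height * 0.1)
        return (mx, my, self.width - mx, self.height - my)


def _ellipse_coverage(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
    supersample: int = 4,
) -> np.ndarray:
    """Anti-aliased coverage (0..1) of a rotated ellipse on a pixel grid."""
    h, w = shape
    cx, cy = center
    a, b = semi_axes
    pad = int(np.ceil(max(a, b))) + 2
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    cov = np.zeros(shape, dtype=np.float64)
    if x0 >= x1 or y0 >= y1:
        return cov
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss
    ys = y0 + np.add.outer(np.arange(y1 - y0), offs).ravel()
    xs = x0 + np.add.outer(np.arange(x1 - x0), offs).ravel()
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    sub = inside.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    cov[y0:y1, x0:x1] = sub
    return cov


def _draw_colored_blob(
    img: np.ndarray,
    cov: np.ndarray,
    base_hsv: np.ndarray,
    rng: np.random.Generator,
    pixel_jitter: float = 0.02,
) -> None:
    """Alpha-blend a blob of per-pixel-jittered color into ``img`` in place."""
    ys, xs = np.nonzero(cov > 0)
    if ys.size == 0:
        return
    n = ys.size
    hsv = np.tile(base_hsv, (n, 1))
    hsv[:, 1:] += rng.normal(0.0, pixel_jitter, (n, 2))
    hsv[:, 0] += rng.normal(0.0, pixel_jitter * 60.0, n)
    hsv[:, 1:] = np.clip(hsv[:, 1:], 0.0, 1.0)
    rgb = hsv_to_rgb_u8(hsv).astype(np.float64)
    alpha = cov[ys, xs][:, None]
    img[ys, xs] = img[ys, xs] * (1 - alpha) + rgb * alpha


def _sample_insect_hsv(model: tuple, rng: np.random.Generator) -> np.ndarray:
    mean, sd = model
    hsv = np.array(mean, dtype=np.float64) + np.array(sd) * rng.normal(size=3)
    hsv[0] %= 360.0
    gain = 1.0 + BRIGHTNESS_JITTER_SD * rng.normal()
    hsv[2] = np.clip(hsv[2] * gain, 0.0, 1.0)
    hsv[1] = np.clip(hsv[1], 0.0, 1.0)
    return hsv


def generate_scene(
    spec: SceneSpec, return_masks: bool = False
) -> tuple[TrapImage, pd.DataFrame] | tuple[TrapImage, pd.DataFrame, list[np.ndarray]]:
    """Render a scene and its per-insect annotations.

    Annotations carry (x, y) center, rendered pixel area (coverage >= 0.5)
    and class label; they describe the insect layer before any noise is
    applied, and are identical across noise settings for a fixed seed.
    With ``return_masks`` the per-insect boolean masks are also returned.
    """
    layout_rng = np.random.default_rng([spec.seed, 0])
    noise_rng = np.random.default_rng([spec.seed, 1])
    h, w = spec.height, spec.width
    tx0, ty0, tx1, ty1 = spec.resolved_trap_bbox()

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = OUTSIDE_RGB
    img[ty0:ty1, tx0:tx1] = hsv_to_rgb_u8(np.array(TRAP_HSV)).astype(np.float64)

    # under-layer noise: bulk smears and stripes
    trap_area = (tx1 - tx0) * (ty1 - ty0)
    for _ in range(spec.noise.bulk_blob_count):
        area = noise_rng.uniform(300, 1500)
        ecc = noise_rng.uniform(1.0, 2.0)
        b = np.sqrt(area / (np.pi * ecc))
        cov = _ellipse_coverage(
            (h, w),
            (noise_rng.uniform(tx0, tx1), noise_rng.uniform(ty0, ty1)),
            (ecc * b, b),
            noise_rng.uniform(0, np.pi),
        )
        # whitened smear: desaturate toward light gray
        alpha = (cov * 0.45)[..., None]
        img = img * (1 - alpha) + np.array([235.0, 232.0, 215.0]) * alpha
    for _ in range(spec.noise.stripe_count):
        x_a = noise_rng.uniform(tx0, tx1)
        y_a = noise_rng.uniform(ty0, ty1)
        ang = noise_rng.uniform(0, np.pi)
        length = noise_rng.uniform(40, 140)
        width = noise_rng.uniform(1.0, 3.0)
        x_b, y_b = x_a + length * np.cos(ang), y_a + length * np.sin(ang)
        yy, xx = np.mgrid[0:h, 0:w]
        # distance to the segment AB
        ab = np.array([x_b - x_a, y_b - y_a])
        t = np.clip(((xx - x_a) * ab[0] + (yy - y_a) * ab[1]) / (ab @ ab), 0, 1)
        d = np.hypot(xx - (x_a + t * ab[0]), yy - (y_a + t * ab[1]))
        cov = np.clip(width / 2 + 0.5 - d, 0, 1)
        shade = noise_rng.choice([-40.0, 30.0])
        img += cov[..., None] * shade

    # insects
    min_a, max_a = spec.insect_area_range
    placed: list[tuple[float, float, float]] = []  # (cx, cy, major axis)
    annotations = []
    masks: list[np.ndarray] = []
    labels = ["whitefly"] * spec.n_whitefly + ["thrips"] * spec.n_thrips
    for label in labels:
        model = spec.whitefly_color_model if label == "whitefly" else spec.thrips_color_model
        area = layout_rng.uniform(min_a, max_a)
        ecc = layout_rng.uniform(1.0, 2.5)
        b = np.sqrt(area / (np.pi * ecc))
        a = ecc * b
        for attempt in range(1000):
            cx = layout_rng.uniform(tx0 + a + 2, tx1 - a - 2)
            cy = layout_rng.uniform(ty0 + a + 2, ty1 - a - 2)
            if all(np.hypot(cx - px, cy - py) > a + pa + 3 for px, py, pa in placed):
                break
        else:
            raise PlacementError(
                f"could not place insect {len(placed) + 1} after 1000 attempts"
            )
        angle = layout_rng.uniform(0, np.pi)
        cov = _ellipse_coverage((h, w), (cx, cy), (a, b), angle)
        _draw_colored_blob(img, cov, _sample_insect_hsv(model, layout_rng), layout_rng)
        mask = cov >= 0.5
        ys, xs = np.nonzero(mask)
        annotations.append(
            {
                "x": float(xs.mean()),
                "y": float(ys.mean()),
                "area": int(mask.sum()),
                "label": label,
            }
        )
        placed.append((cx, cy, a))
        if return_masks:
            masks.append(mask)

    # over-layer noise: glue spots on top of everything
    n_spots = int(round(spec.noise.spot_density * trap_area / 1e4))
    for _ in range(n_spots):
        area = noise_rng.uniform(4, 30)
        ecc = noise_rng.uniform(1.0, 2.0)
        b = np.sqrt(area / (np.pi * ecc))
        cov = _ellipse_coverage(
            (h, w),
            (noise_rng.uniform(tx0, tx1), noise_rng.uniform(ty0, ty1)),
            (ecc * b, b),
            noise_rng.uniform(0, np.pi),
        )
        _draw_colored_blob(img, cov, _sample_insect_hsv(GLUE_SPOT_COLOR, noise_rng), noise_rng)

    # illumination gradient and reflection
    g = spec.noise.illumination_gradient
    if g > 0:
        ang = noise_rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        t = (xx * np.cos(ang) + yy * np.sin(ang))
        t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
        img *= (1.0 + g * (t - 0.5))[..., None]
    if spec.noise.reflection_patch is not None:
        (rx0, ry0, rx1, ry1), gain = spec.noise.reflection_patch
        img[ry0:ry1, rx0:rx1] *= gain

    if spec.illumination_gain is not None:
        img *= float(spec.illumination_gain)

    img += noise_rng.normal(0.0, SENSOR_NOISE_SD, img.shape)
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    frame = pd.DataFrame(annotations, columns=["x", "y", "area", "label"])
    image = TrapImage(pixels=pixels)
    if return_masks:
        return image, frame, masks
    return image, frame


def generate_training_set(
    n_per_class: int,
    crop: int = 32,
    seed: int = 0,
    spec: SceneSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Render ``n_per_class`` labeled crops per class (3 classes).

    Insect crops hold one centered animal on card background; background
    crops alternate between a centered glue spot and clean card.  Crops are
    rendered with the same color/noise models as full scenes and per-crop
    brightness jitter, and a fraction of them sit on degraded card (smear
    wash or stripe) just as insects in a real frame do — a classifier
    trained only on clean backgrounds drops exactly those animals.  With
    ``out_dir`` the crops are also written as PNGs next to a
    ``labels.csv``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    spec = spec or SceneSpec()
    rng = np.random.default_rng([seed, 2])
    crops: list[np.ndarray] = []
    labels: list[str] = []
    min_a, max_a = spec.insect_area_range
    for i in range(n_per_class):
        for label in ("whitefly", "thrips", "background"):
            card_hsv = np.array(TRAP_HSV) + np.array(TRAP_HSV_SD) * rng.normal(size=3)
            card_hsv[1:] = np.clip(card_hsv[1:], 0.0, 1.0)
            img = np.empty((crop, crop, 3), dtype=np.float64)
            img[:] = hsv_to_rgb_u8(card_hsv).astype(np.float64)
            u = rng.uniform()
            if u < 0.25:  # partial glue smear wash
                alpha = rng.uniform(0.1, 0.45)
                img = img * (1 - alpha) + np.array([235.0, 232.0, 215.0]) * alpha
            elif u < 0.4:  # stripe crossing the tile
                yy, xx = np.mgrid[0:crop, 0:crop]
                ang = rng.uniform(0, np.pi)
                d = np.abs(
                    (xx - crop / 2) * np.sin(ang) - (yy - crop / 2) * np.cos(ang)
                ) - rng.uniform(0, crop / 4)
                cov = np.clip(rng.uniform(0.5, 1.5) + 0.5 - np.abs(d), 0, 1)
                img += cov[..., None] * rng.choice([-40.0, 30.0])
            center = (crop / 2 + rng.uniform(-1, 1), crop / 2 + rng.uniform(-1, 1))
            if label == "background":
                if i % 2 == 0:  # centered glue spot
                    area = rng.uniform(5, 25)
                    ecc = rng.uniform(1.0, 2.0)
                    b = np.sqrt(area / (np.pi * ecc))
                    cov = _ellipse_coverage(
                        (crop, crop), center, (ecc * b, b), rng.uniform(0, np.pi)
                    )
                    _draw_colored_blob(img, cov, _sample_insect_hsv(GLUE_SPOT_COLOR, rng), rng)
            else:
                model = (
                    spec.whitefly_color_model if label == "whitefly" else spec.thrips_color_model
                )
                area = rng.uniform(min_a, max_a)
                ecc = rng.uniform(1.0, 2.5)
                b = np.sqrt(area / (np.pi * ecc))
                cov = _ellipse_coverage(
                    (crop, crop), center, (ecc * b, b), rng.uniform(0, np.pi)
                )
                _draw_colored_blob(img, cov, _sample_insect_hsv(model, rng), rng)
            img *= _crop_gain(rng)
            img += rng.normal(0.0, SENSOR_NOISE_SD, img.shape)
            crops.append(np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8))
            labels.append(label)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for j, (c, lab) in enumerate(zip(crops, labels)):
            name = f"crop_{j:05d}.png"
            iio.imwrite(out / name, c)
            rows.append({"file": name, "label": lab})
        pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    return crops, labels


def noise_sweep(
    base: SceneSpec, scales: list[float]
) -> list[tuple[float, TrapImage, pd.DataFrame]]:
    """Render the same insect layout under increasingly degraded conditions.

    Each entry scales every noise rate of the base spec by one factor
    (1.0 reproduces the base scene exactly); the insect layout and hence
    the annotations are identical across entries.
    """
    if list(scales) != sorted(scales):
        raise ValueError("scales must be in ascending order")
    out = []
    for s in scales:
        scene_spec = replace(base, noise=base.noise.scaled(s))
        image, ann = generate_scene(scene_spec)
        out.append((float(s), image, ann))
    return out
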