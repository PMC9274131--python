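"""Scoring detections against ground truth.

Detection quality is summarized per class by the true positive rate
TPR = TP / (TP + FN), the false positive rate FPR = FP / (TN + FP) and the
accuracy (TP + TN) / (TP + TN + FP + FN).  A detection task has no natural
"true negative", so the evaluation universe is defined as the union of all
matched and unmatched objects of all classes — background candidate
regions count as objects, mirroring the three-class framing in which
"background" is itself a predicted category.

Detections are matched to ground-truth objects one-to-one by ascending
centroid distance (greedy), accepting pairs within ``max_dist`` pixels.
Centroid distance is preferred over IoU because 5-25 px objects make IoU
numerically unstable.  Counting agreement between the automatic and a
manual count across images is summarized by an ordinary least-squares fit
and its coefficient of determination R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .classifier import CLASSES


@dataclass
class Detection:
    """One classified region in global image coordinates."""

    bbox: tuple[int, int, int, int]  # x0, y0, x1, y1 half-open
    label: str
    centroid: tuple[float, float] | None = None
    region_ref: int | None = None

    def center(self) -> tuple[float, float]:
        if self.centroid is not None:
            return self.centroid
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class DetectionSet:
    """All detections of one image plus derived per-class counts."""

    detections: list[Detection]
    image_id: str = ""

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for d in self.detections:
            out[d.label] = out.get(d.label, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.detections):
            cx, cy = d.center()
            rows.append(
                {
                    "image_id": self.image_id,
                    "x0": d.bbox[0],
                    "y0": d.bbox[1],
                    "x1": d.bbox[2],
                    "y1": d.bbox[3],
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "label": d.label,
                    "region_ref": i if d.region_ref is None else d.region_ref,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "image_id", "x0", "y0", "x1", "y1",
                "centroid_x", "centroid_y", "label", "region_ref",
            ],
        )


@dataclass
class GroundTruth:
    """Manual annotations: one (x, y, label) point per object."""

    points: list[tuple[float, float, str]]
    image_id: str = ""

    @classmethod
    def from_frame(cls, df: pd.DataFrame, image_id: str = "") -> "GroundTruth":
        return cls(
            points=[(float(r.x), float(r.y), str(r.label)) for r in df.itertuples()],
            image_id=image_id,
        )

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, lab in self.points:
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class MatchResult:
    matches: list[tuple[int, int, float]]  # (detection idx, truth idx, distance)
    unmatched_detections: list[int]
    unmatched_truth: list[int]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


@dataclass
class Rates:
    tpr: float | None
    fpr: float | None
    accuracy: float | None


def match_detections(
    detections: DetectionSet, truth: GroundTruth, max_dist: float = 8.0
) -> MatchResult:
    """Greedy one-to-one matching by ascending centroid distance.

    Pairs farther apart than ``max_dist`` px are never matched.  Labels are
    ignored here — class agreement is settled by the confusion accounting.
    """
    det_xy = np.array([d.center() for d in detections.detections], dtype=float).reshape(-1, 2)
    tru_xy = np.array([(x, y) for x, y, _ in truth.points], dtype=float).reshape(-1, 2)
    n_d, n_t = len(det_xy), len(tru_xy)
    if n_d == 0 or n_t == 0:
        return MatchResult([], list(range(n_d)), list(range(n_t)))

    dist = np.linalg.norm(det_xy[:, None, :] - tru_xy[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for di, ti in order:
        d = dist[di, ti]
        if d > max_dist:
            break
        if di in used_d or ti in used_t:
            continue
        matches.append((int(di), int(ti), float(d)))
        used_d.add(int(di))
        used_t.add(int(ti))
    return MatchResult(
        matches=matches,
        unmatched_detections=[i for i in range(n_d) if i not in used_d],
        unmatched_truth=[i for i in range(n_t) if i not in used_t],
    )


def confusion_from_matches(
    result: MatchResult,
    detections: DetectionSet,
    truth: GroundTruth,
    classes: tuple[str, ...] = CLASSES,
) -> dict[str, ConfusionCounts]:
    """Per-class confusion counts over the matched-object universe.

    For class c: TP = matched pairs labeled c on both sides; FN = truth c
    that went unmatched or matched a non-c detection; FP = detections c
    that failed to match a truth c; TN = the rest of the universe.  The
    universe size (TP+FP+TN+FN) is identical for every class.
    """
    universe = len(result.matches) + len(result.unmatched_detections) + len(
        result.unmatched_truth
    )
    out = {}
    for c in classes:
        tp = fp = fn = 0
        for di, ti, _ in result.matches:
            dlab = detections.detections[di].label
            tlab = truth.points[ti][2]
            if tlab == c and dlab == c:
                tp += 1
            elif tlab == c and dlab != c:
                fn += 1
            elif tlab != c and dlab == c:
                fp += 1
        fn += sum(1 for ti in result.unmatched_truth if truth.points[ti][2] == c)
        fp += sum(
            1 for di in result.unmatched_detections if detections.detections[di].label == c
        )
        out[c] = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=universe - tp - fp - fn)
    return out


def rates(counts: ConfusionCounts) -> Rates:
    """TPR, FPR and accuracy; a zero denominator yields None, never 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    fpr = fp / (tn + fp) if (tn + fp) > 0 else None
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total > 0 else None
    return Rates(tpr=tpr, fpr=fpr, accuracy=acc)


def count_regression(
    auto_counts: np.ndarray, manual_counts: np.ndarray
) -> tuple[float, float, float]:
    """OLS of automatic on manual counts: returns (slope, intercept, R²)."""
    auto = np.asarray(auto_counts, dtype=float)
    manual = np.asarray(manual_counts, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual counts must be equal-length 1-D arrays")
    if auto.size < 3:
        raise ValueError("count regression needs at least 3 images")
    if np.allclose(manual, manual[0]):
        raise ValueError("manual counts have zero variance")
    fit = _stats.linregress(manual, auto)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def ground_truth_to_coco(truths: list[GroundTruth], box_half_side: int = 4) -> dict:
    """Export point annotations as a COCO-style dict (bbox variant).

    Points become ``2 * box_half_side`` square boxes centered on the
    object, matching the annotation convention for targets of known scale.
    """
    categories = [{"id": i + 1, "name": c} for i, c in enumerate(CLASSES)]
    cat_id = {c: i + 1 for i, c in enumerate(CLASSES)}
    images, annotations = [], []
    ann_id = 1
    for img_id, truth in enumerate(truths, start=1):
        images.append({"id": img_id, "file_name": truth.image_id})
        for x, y, label in truth.points:
            side = 2 * box_half_side
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_id[label],
                    "bbox": [x - box_half_side, y - box_half_side, side, side],
                    "area": side * side,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {"images": images, "annotations": annotations, "categories": categories}


def ground_truth_from_coco(payload: dict) -> list[GroundTruth]:
    """Inverse of :func:`ground_truth_to_coco` (bbox centers become points)."""
    cat_name = {c["id"]: c["name"] for c in payload["categories"]}
    by_image: dict[int, GroundTruth] = {
        img["id"]: GroundTruth(points=[], image_id=img["file_name"])
        for img in payload["images"]
    }
    for ann in payload["annotations"]:
        x, y, w, h = ann["bbox"]
        by_image[ann["image_id"]].points.append(
            (x + w / 2.0, y + h / 2.0, cat_name[ann["category_id"]])
        )
    return [by_image[k] for k in sorted(by_image)]


def plot_count_regression(
    auto_counts: np.ndarray,
    manual_counts: np.ndarray,
    out_path,
    label: str = "",
) -> tuple[float, float, float]:
    """Scatter of automatic vs manual counts with the OLS fit line.

    Returns (slope, intercept, R^2) of the plotted fit.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slope, intercept, r2 = count_regression(auto_counts, manual_counts)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(manual_counts, auto_counts, s=25, color="tab:blue", zorder=3)
    xs = np.linspace(0, max(np.max(manual_counts), np.max(auto_counts)) * 1.05, 50)
    ax.plot(xs, slope * xs + intercept, "k-", lw=1)
    ax.plot(xs, xs, "k:", lw=0.8, alpha=0.5)
    ax.set_xlabel("manual count")
    ax.set_ylabel("automatic count")
    title = f"{label}  y = {slope:.2f}x + {intercept:.2f},  $R^2$ = {r2:.4f}"
    ax.set_title(title.strip(), fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return slope, intercept, r2


def evaluate_images(
    detection_sets: list[DetectionSet],
    truths: list[GroundTruth],
    classes: tuple[str, ...] = CLASSES,
    max_dist: float = 8.0,
) -> dict:
    """Per-image rates, their mean ± SD, and per-class count regression.

    The summary mirrors the usual reporting shape for a multi-image
    benchmark: per-class TPR/FPR/accuracy as mean ± SD over images, plus
    slope/intercept/R² of automatic vs manual counts for each target class.
    """
    by_id = {t.image_id: t for t in truths}
    per_image_rows = []
    auto_counts: dict[str, list[int]] = {c: [] for c in classes}
    manual_counts: dict[str, list[int]] = {c: [] for c in classes}
    overlapping = [ds for ds in detection_sets if ds.image_id in by_id]
    if not overlapping:
        raise ValueError("no overlapping image_ids between detections and truth")
    for ds in overlapping:
        truth = by_id[ds.image_id]
        res = match_detections(ds, truth, max_dist=max_dist)
        conf = confusion_from_matches(res, ds, truth, classes=classes)
        for c in classes:
            r = rates(conf[c])
            per_image_rows.append(
                {
                    "image_id": ds.image_id,
                    "class": c,
                    "tpr": r.tpr,
                    "fpr": r.fpr,
                    "accuracy": r.accuracy,
                }
            )
        det_counts = ds.counts
        tru_counts = truth.counts()
        for c in classes:
            auto_counts[c].append(det_counts.get(c, 0))
            manual_counts[c].append(tru_counts.get(c, 0))

    per_image = pd.DataFrame(per_image_rows)
    summary = (
        per_image.groupby("class", sort=False)[["tpr", "fpr", "accuracy"]]
        .agg(["mean", "std"])
    )
    regression = {}
    for c in classes:
        manual = np.array(manual_counts[c])
        if manual.size >= 3 and not np.allclose(manual, manual[0]):
            slope, intercept, r2 = count_regression(np.array(auto_counts[c]), manual)
            regression[c] = {"slope": slope, "intercept": intercept, "r_squared": r2}
    return {
        "per_image": per_image,
        "summary": summary,
        "count_regression": regression,
        "n_images": len(overlapping),
    }
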