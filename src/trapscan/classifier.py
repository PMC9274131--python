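"""Three-class maximum-margin identification: whitefly / thrips / background.

Candidate regions are described by a 3-dim mean-color vector and separated
with a soft-margin support vector classifier (C-SVC semantics, one-vs-one
multiclass reduction — the native scheme of the underlying libsvm solver).
Features are standardized to zero mean / unit variance on the training set
only; margins are meaningless when one axis spans 360 degrees and another
spans 1.

The kernel and its hyperparameters are deliberately configuration, not
constants: the default RBF with C = 10 and gamma = "scale" handles the
compact-but-curved class clusters seen in HSV, and `cross_validate`
provides the protocol for choosing anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector

CLASSES = ("whitefly", "thrips", "background")

MODEL_FORMAT_VERSION = 1


@dataclass
class SVMConfig:
    """Hyperparameters of the C-SVC classifier."""

    kernel: str = "rbf"
    C: float = 10.0
    gamma: float | str = "scale"
    degree: int = 3  # only used by the polynomial kernel
    #: inverse-frequency reweighting; the background class is sampled far
    #: more densely than the insect classes and would otherwise dominate
    class_weight: str | dict | None = "balanced"


@dataclass
class LabeledSample:
    features: FeatureVector
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not in {CLASSES}")


@dataclass
class ClassifierModel:
    """A fitted scaler + C-SVC pair with its class order."""

    scaler: StandardScaler
    svc: SVC
    classes: tuple[str, ...]
    config: SVMConfig = field(default_factory=SVMConfig)
    space: str = "HSV"

    def save(self, path: str | Path) -> None:
        """Persist as a versioned archive (joblib payload + plain header)."""
        payload = {
            "header": {
                "format_version": MODEL_FORMAT_VERSION,
                "classes": list(self.classes),
                "space": self.space,
                "kernel": self.config.kernel,
                "C": self.config.C,
                "gamma": self.config.gamma,
            },
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "svc": self.svc,
            "config": self.config,
            "scaler": self.scaler,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = joblib.load(path)
        version = payload["header"]["format_version"]
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        return cls(
            scaler=payload["scaler"],
            svc=payload["svc"],
            classes=tuple(payload["header"]["classes"]),
            config=payload["config"],
            space=payload["header"]["space"],
        )


def _as_xy(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([s.features.values for s in samples], dtype=np.float64)
    y = np.array([s.label for s in samples])
    return X, y


def train(
    samples: list[LabeledSample],
    config: SVMConfig | None = None,
    seed: int = 0,
    space: str = "HSV",
) -> ClassifierModel:
    """Fit the scaler and the one-vs-one C-SVC on labeled feature vectors.

    Requires at least two classes with >= 5 samples each and finite
    features.  Given identical inputs and seed the fit is deterministic.
    """
    config = config or SVMConfig()
    X, y = _as_xy(samples)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    present, counts = np.unique(y, return_counts=True)
    if len(present) < 2:
        raise ValueError("training needs at least two classes")
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 training samples")

    scaler = StandardScaler().fit(X)
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        degree=config.degree,
        class_weight=config.class_weight,
        decision_function_shape="ovo",
        random_state=seed,
    )
    svc.fit(scaler.transform(X), y)
    # class order: the canonical whitefly/thrips/background order restricted
    # to the classes present, used for tie-breaks and reports
    classes = tuple(c for c in CLASSES if c in present)
    return ClassifierModel(scaler=scaler, svc=svc, classes=classes, config=config, space=space)


def predict(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Predict one label per feature row (vote ties go to the first class)."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 1:
        features = features.reshape(1, -1)
    if features.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match the "
            f"model's {model.scaler.mean_.shape[0]}"
        )
    return model.svc.predict(model.scaler.transform(features))


def cross_validate(
    samples: list[LabeledSample],
    k: int = 5,
    config: SVMConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold per-class TPR / FPR / accuracy.

    Each fold fits a fresh scaler + SVC on the training split (no leakage)
    and scores the held-out split with the same one-vs-rest confusion
    accounting used for detections.  Returns a tidy frame with one row per
    (fold, class) plus an "overall" accuracy row per fold.
    """
    from .evaluation import ConfusionCounts, rates

    config = config or SVMConfig()
    X, y = _as_xy(samples)
    present, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError("every class needs at least k samples for k folds")

    rows = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_samples = [samples[i] for i in tr]
        model = train(fold_samples, config=config, seed=seed)
        pred = predict(model, X[te])
        truth = y[te]
        for cls in model.classes:
            tp = int(np.sum((pred == cls) & (truth == cls)))
            fp = int(np.sum((pred == cls) & (truth != cls)))
            fn = int(np.sum((pred != cls) & (truth == cls)))
            tn = len(te) - tp - fp - fn
            r = rates(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            rows.append(
                {
                    "fold": fold,
                    "class": cls,
                    "tpr": r.tpr,
                    "fpr": r.fpr,
                    "accuracy": r.accuracy,
                }
            )
        rows.append(
            {
                "fold": fold,
                "class": "overall",
                "tpr": np.nan,
                "fpr": np.nan,
                "accuracy": float(np.mean(pred == truth)),
            }
        )
    return pd.DataFrame(rows)
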