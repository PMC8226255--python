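"""Marker classification of detected cells.

Two routes, mirroring common digital-pathology practice:

* a *single measurement classifier* — one feature (typically the cell-mean
  intensity of a marker), one threshold; and
* a point-trained *object classifier* — a random forest over the cell's full
  feature vector (compartment means plus neighborhood-smoothed features),
  trained from manually assigned points of a positive class and an ``ignore``
  class.  Fewer than 100 points per class triggers a warning, since accuracy
  measurably improves with at least that many.

Composite phenotypes use set-intersection semantics: a beta cell is
INS+ ∧ PI+; T-cell subsets are gated in two stages (a CD8 call is only made
on CD3+ cells), so CD4 (CD3+CD8−) = CD3+ \\ CD8+ exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cells import feature_columns

__all__ = ["SingleMeasurementClassifier", "ObjectClassifier", "TrainingPoints",
           "apply_threshold_classifier", "combine_classifiers",
           "train_object_classifier", "apply_object_classifier",
           "classify_T_cells", "cd4_count", "RECOMMENDED_MIN_POINTS"]

log = logging.getLogger(__name__)

RECOMMENDED_MIN_POINTS = 100


@dataclass
class SingleMeasurementClassifier:
    """One-feature threshold rule: label ``output_class`` iff feature > threshold."""

    feature: str
    threshold: float
    output_class: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold) and not np.isinf(self.threshold):
            raise ValueError("threshold must be a number")


def apply_threshold_classifier(cells: pd.DataFrame,
                               clf: SingleMeasurementClassifier) -> pd.DataFrame:
    """Add ``{output_class}`` boolean column; idempotent."""
    if clf.feature not in cells.columns:
        raise ValueError(f"unknown feature {clf.feature!r}; available: "
                         f"{feature_columns(cells)}")
    cells[clf.output_class] = cells[clf.feature].to_numpy() > clf.threshold
    return cells


def combine_classifiers(cells: pd.DataFrame, output_class: str,
                        markers_all_of: list[str]) -> pd.DataFrame:
    """Composite class = AND over component classes (order-independent)."""
    cols = [f"{m}+" if not m.endswith(("+", "-")) else m
            for m in markers_all_of]
    for c in cols:
        if c not in cells.columns:
            raise ValueError(f"component class {c!r} not assigned yet")
    combined = np.ones(len(cells), dtype=bool)
    for c in cols:
        combined &= cells[c].to_numpy(dtype=bool)
    cells[output_class] = combined
    return cells


@dataclass
class TrainingPoints:
    """Point annotations: (cell id, class) pairs with both classes present."""

    points: pd.DataFrame      # columns: cell_id, class

    def __post_init__(self) -> None:
        req = {"cell_id", "class"}
        if not req <= set(self.points.columns):
            raise ValueError("training points need cell_id and class columns")

    def classes(self) -> list[str]:
        return sorted(self.points["class"].unique())


@dataclass
class ObjectClassifier:
    model: RandomForestClassifier
    features: list[str]
    positive_class: str
    n_points_per_class: dict[str, int]
    seed: int
    version: str = "1"

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ObjectClassifier":
        return joblib.load(path)


def train_object_classifier(cells: pd.DataFrame, points: TrainingPoints,
                            seed: int = 0,
                            features: list[str] | None = None,
                            n_estimators: int = 100,
                            max_depth: int = 12) -> ObjectClassifier:
    """Fit the tree ensemble on the annotated cells' full feature vectors."""
    classes = points.classes()
    if len(classes) < 2:
        raise ValueError("need training points for both classes "
                         f"(got only {classes})")
    feats = features if features is not None else feature_columns(cells)
    if not feats:
        raise ValueError("no intensity features on cells; run measure_cells "
                         "and add_smoothed_features first")
    merged = points.points.merge(cells, on="cell_id", how="inner")
    if len(merged) < len(points.points):
        missing = set(points.points["cell_id"]) - set(cells["cell_id"])
        raise ValueError(f"training points reference unknown cells: "
                         f"{sorted(missing)[:5]}...")
    counts = merged["class"].value_counts().to_dict()
    for cls, n in counts.items():
        if n < RECOMMENDED_MIN_POINTS:
            log.warning("class %r has %d training points; >=%d recommended "
                        "for accuracy", cls, n, RECOMMENDED_MIN_POINTS)
    X = merged[feats].to_numpy(dtype=float)
    y = (merged["class"] != "ignore").to_numpy()
    positive = next(c for c in classes if c != "ignore")
    model = RandomForestClassifier(n_estimators=n_estimators,
                                   max_depth=max_depth,
                                   random_state=int(seed) & 0x7FFFFFFF,
                                   n_jobs=1)
    model.fit(X, y)
    return ObjectClassifier(model=model, features=feats,
                            positive_class=positive,
                            n_points_per_class={str(k): int(v)
                                                for k, v in counts.items()},
                            seed=seed)


def apply_object_classifier(cells: pd.DataFrame, clf: ObjectClassifier,
                            subset: np.ndarray | None = None) -> pd.DataFrame:
    """Add the classifier's positive-class column (optionally gated)."""
    X = cells[clf.features].to_numpy(dtype=float)
    pred = np.zeros(len(cells), dtype=bool)
    sel = np.ones(len(cells), dtype=bool) if subset is None \
        else np.asarray(subset, dtype=bool)
    if sel.any():
        pred[sel] = clf.model.predict(X[sel])
    cells[clf.positive_class] = pred
    return cells


def classify_T_cells(cells: pd.DataFrame, clf_cd3, clf_cd8) -> pd.DataFrame:
    """Two-stage T-cell gating: CD8 is evaluated only on CD3+ cells.

    Adds ``CD3+``, ``CD3+CD8+`` and ``CD3+CD8-`` (CD4) columns forming an
    exact partition of the CD3+ set.
    """
    cells = _apply_either(cells, clf_cd3)
    cd3 = cells[_class_of(clf_cd3)].to_numpy(dtype=bool)
    if isinstance(clf_cd8, ObjectClassifier):
        cells = apply_object_classifier(cells, clf_cd8, subset=cd3)
    else:
        cells = apply_threshold_classifier(cells, clf_cd8)
    cd8_raw = cells[_class_of(clf_cd8)].to_numpy(dtype=bool)
    cells["CD3+"] = cd3
    cells["CD3+CD8+"] = cd3 & cd8_raw
    cells["CD3+CD8-"] = cd3 & ~cd8_raw
    cells[_class_of(clf_cd8)] = cells["CD3+CD8+"]   # enforce the gate
    return cells


def _apply_either(cells, clf):
    if isinstance(clf, ObjectClassifier):
        return apply_object_classifier(cells, clf)
    return apply_threshold_classifier(cells, clf)


def _class_of(clf) -> str:
    return clf.positive_class if isinstance(clf, ObjectClassifier) \
        else clf.output_class


def precision_recall(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int((pred & truth).sum())
    prec = tp / pred.sum() if pred.sum() else 1.0
    rec = tp / truth.sum() if truth.sum() else 1.0
    return prec, rec


def threshold_recall_at_precision(scores: np.ndarray, truth: np.ndarray,
                                  min_precision: float) -> float:
    """Best recall any single intensity threshold achieves while keeping
    precision ≥ ``min_precision`` (the thresholding-vs-ML comparison)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    best = 0.0
    for thr in np.unique(scores):
        pred = scores > thr
        if not pred.any():
            continue
        prec, rec = precision_recall(pred, truth)
        if prec >= min_precision:
            best = max(best, rec)
    return best


def cd4_count(n_cd3: int, n_cd8: int) -> int:
    """CD4 (CD3+CD8−) count = CD3+ − CD8+ under two-stage gating."""
    if n_cd8 > n_cd3:
        raise ValueError("CD8+ count cannot exceed CD3+ count under gating")
    return int(n_cd3) - int(n_cd8)
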