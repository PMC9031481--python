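"""Experimental protocol: augmentation, cross-validation, and metrics.

Reproduces the evaluation pipeline the gesture classifier is assessed
with: sevenfold rotation augmentation (three magnitudes in both directions
plus the original), five-fold cross-validation with optional original-frame
grouping, the per-class one-vs-rest metrics, and the per-palsy-grade
breakdown.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold, StratifiedKFold

from .classifier import MLPHyperparams, predict_batch, train_mlp
from .data import GestureDataset, N_CLASSES
from .features import compute_features
from .landmarks import rotate_landmarks, tilt_correct

__all__ = [
    "DEFAULT_ROTATION_MAGNITUDES",
    "ConfusionCounts",
    "ClassMetrics",
    "FoldResult",
    "EvalReport",
    "extract_features",
    "augment_with_rotations",
    "stratified_group_kfold",
    "classification_metrics",
    "run_cv_experiment",
    "run_per_grade_experiment",
]

#: Small in-plane tilts, matching the regime the tilt correction handles.
DEFAULT_ROTATION_MAGNITUDES: tuple[float, ...] = (5.0, 10.0, 15.0)


def extract_features(ds: GestureDataset) -> GestureDataset:
    """Tilt-correct every landmark sample and attach its feature vector."""
    out = []
    for s in ds:
        if s.landmarks is None:
            raise ValueError(f"sample {s.provenance.original_id} has no landmarks")
        out.append(s.replace(features=compute_features(tilt_correct(s.landmarks))))
    return GestureDataset(out)


def augment_with_rotations(
    ds: GestureDataset,
    magnitudes: Sequence[float] = DEFAULT_ROTATION_MAGNITUDES,
) -> GestureDataset:
    """Add rotated copies of every sample: one per signed angle.

    For ``m`` magnitudes the output holds ``(2m + 1) * len(ds)`` samples —
    each original plus copies at +a and -a for every magnitude, tagged with
    their provenance so group-aware splitting can keep them together.
    Labels, grades, and subjects are preserved.  An empty magnitude list
    returns the input unchanged.
    """
    if len(ds) == 0:
        raise ValueError("cannot augment an empty dataset")
    magnitudes = [float(a) for a in magnitudes]
    if any(a <= 0 for a in magnitudes):
        raise ValueError("rotation magnitudes must be positive")
    if not magnitudes:
        return ds
    out = []
    for s in ds:
        out.append(s)
        for a in magnitudes:
            for angle in (a, -a):
                prov = dataclasses.replace(s.provenance, angle_deg=angle)
                if s.landmarks is not None:
                    lm = rotate_landmarks(s.landmarks, angle)
                    out.append(s.replace(landmarks=lm, features=None, provenance=prov))
                else:
                    # feature-only dataset: rotation leaves tilt-corrected
                    # features unchanged, so the copy reuses them
                    out.append(s.replace(provenance=prov))
    return GestureDataset(out)


def stratified_group_kfold(
    ds: GestureDataset, k: int = 5, seed: int = 0, *, group: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-stratified k-fold split of the dataset indices.

    With ``group=True`` (default) all augmented copies of one original frame
    are kept in the same fold, preventing train/test leakage of
    near-duplicate samples.  ``group=False`` gives a plain stratified split
    over individual samples (the arithmetic of equal 560-sample folds on a
    2800-sample set needs this mode).  If some class has fewer groups than
    folds, a warning is issued and a group-only split is used as fallback.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = ds.labels
    idx_dummy = np.zeros((len(ds), 1))
    if not group:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(idx_dummy, y)]
    groups = np.asarray(ds.groups)
    # group-level class counts decide whether stratification is feasible
    for cls in np.unique(y):
        if len(np.unique(groups[y == cls])) < k:
            warnings.warn(
                f"class {cls} has fewer than {k} groups; "
                "falling back to an unstratified group split",
                stacklevel=2,
            )
            splitter = GroupKFold(n_splits=k)
            return [(tr, te) for tr, te in splitter.split(idx_dummy, y, groups)]
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(idx_dummy, y, groups)]


# --------------------------------------------------------------------------
# metrics


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """6x6 confusion matrix; rows are actual labels, columns predicted."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(m < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = N_CLASSES) -> "ConfusionCounts":
        m = np.zeros((n_classes, n_classes), dtype=int)
        for t, p in zip(np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)):
            m[t, p] += 1
        return cls(m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def one_vs_rest(self, cls_idx: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one class; they sum to the total count."""
        m = self.matrix
        tp = int(m[cls_idx, cls_idx])
        fn = int(m[cls_idx].sum() - tp)
        fp = int(m[:, cls_idx].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.matrix + other.matrix)


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    recall: float
    precision: float
    f1: float
    zero_denominator: bool = False


@dataclasses.dataclass(frozen=True)
class FoldResult:
    correct: int
    errors: int

    @property
    def accuracy(self) -> float:
        return fold_accuracy(self.correct, self.errors)


def fold_accuracy(correct: int, errors: int) -> float:
    """Accuracy from a (correct, errors) count pair, in [0, 1]."""
    total = correct + errors
    if total <= 0:
        raise ValueError("correct + errors must be positive")
    return correct / total


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_metrics(cm: ConfusionCounts) -> dict:
    """Per-class one-vs-rest recall/precision/F1 and the overall accuracy.

    Zero-denominator metrics are reported as 0 with ``zero_denominator``
    flagged rather than raising mid-batch.
    """
    per_class = []
    for c in range(cm.matrix.shape[0]):
        tp, _tn, fp, fn = cm.one_vs_rest(c)
        recall, z1 = _safe_div(tp, tp + fn)
        precision, z2 = _safe_div(tp, tp + fp)
        f1, z3 = _safe_div(2 * tp, 2 * tp + fp + fn)
        per_class.append(ClassMetrics(recall, precision, f1, z1 or z2 or z3))
    accuracy, _ = _safe_div(int(np.trace(cm.matrix)), cm.total)
    return {"accuracy": accuracy, "per_class": per_class}


@dataclasses.dataclass
class EvalReport:
    """Aggregated cross-validation result."""

    folds: list[FoldResult]
    confusion: ConfusionCounts
    accuracy: float
    per_class: list[ClassMetrics]

    @property
    def total_correct(self) -> int:
        return sum(f.correct for f in self.folds)

    @property
    def total_errors(self) -> int:
        return sum(f.errors for f in self.folds)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "folds": [
                {"correct": f.correct, "errors": f.errors, "accuracy": f.accuracy}
                for f in self.folds
            ],
            "confusion_matrix": self.confusion.matrix.tolist(),
            "per_class": [
                {
                    "recall": c.recall,
                    "precision": c.precision,
                    "f1": c.f1,
                    "zero_denominator": c.zero_denominator,
                }
                for c in self.per_class
            ],
        }


def run_cv_experiment(ds: GestureDataset, hp: MLPHyperparams | None = None,
                      k: int = 5, seed: int = 0, *, group: bool = True) -> EvalReport:
    """Train/evaluate ``k`` models on a k-fold split and pool the results.

    Deterministic given the seed (it drives both the fold assignment and,
    combined with the hyperparameter seed, the network initialization).
    """
    hp = hp or MLPHyperparams()
    X = ds.feature_matrix()
    y = ds.labels
    folds = []
    pooled = ConfusionCounts(np.zeros((N_CLASSES, N_CLASSES), dtype=int))
    for train_idx, test_idx in stratified_group_kfold(ds, k=k, seed=seed, group=group):
        model = train_mlp((X[train_idx], y[train_idx]), hp)
        y_pred, _ = predict_batch(model, X[test_idx])
        cm = ConfusionCounts.from_predictions(y[test_idx], y_pred)
        correct = int(np.trace(cm.matrix))
        folds.append(FoldResult(correct=correct, errors=cm.total - correct))
        pooled = pooled + cm
    frag = classification_metrics(pooled)
    return EvalReport(folds=folds, confusion=pooled,
                      accuracy=frag["accuracy"], per_class=frag["per_class"])


def run_per_grade_experiment(ds: GestureDataset, hp: MLPHyperparams | None = None,
                             k: int = 5, seed: int = 0, *,
                             group: bool = True) -> dict[str, EvalReport]:
    """One independent CV experiment per palsy grade present in the data.

    Grades with too few samples to split are skipped with a warning.
    """
    reports: dict[str, EvalReport] = {}
    for grade in dict.fromkeys(ds.grades):  # preserves first-seen order
        sub = ds.filter_grade(grade)
        try:
            reports[grade] = run_cv_experiment(sub, hp, k=k, seed=seed, group=group)
        except ValueError as exc:
            warnings.warn(f"skipping grade {grade!r}: {exc}", stacklevel=2)
    return reports
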