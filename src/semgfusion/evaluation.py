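"""Evaluation protocol: subject-wise splits and summary statistics.

The split unit is the subject — all trials of a held-out subject go to
the test set, so classification must generalize across individuals, not
merely across repetitions.  Feature-dispersion statistics (quartile
difference, mean absolute deviation, sample standard deviation), Pearson
correlation between class feature profiles, and Tukey box-plot summaries
quantify how distinct the learned class representations are.

Quartiles use linear interpolation between order statistics (numpy's
default, the "type 7" rule); the convention is recorded in report
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import Dataset, Trial

__all__ = [
    "SplitSpec",
    "EvalReport",
    "split_by_subjects",
    "accuracy",
    "confusion",
    "qd",
    "md",
    "stdev",
    "correlation_matrix",
    "five_number_summary",
]

QUARTILE_METHOD = "linear"  # numpy interpolation rule ("type 7")


@dataclass(frozen=True)
class SplitSpec:
    """Held-out test subjects; everyone else trains."""

    test_subjects: frozenset[int]

    def __post_init__(self) -> None:
        if not self.test_subjects:
            raise ValueError("test subject set must be non-empty")


def split_by_subjects(
    dataset: Dataset, spec: SplitSpec
) -> tuple[list[Trial], list[Trial]]:
    """Partition trials so no subject straddles train and test."""
    subjects = set(dataset.subjects)
    missing = set(spec.test_subjects) - subjects
    if missing:
        raise ValueError(f"unknown test subjects: {sorted(missing)}")
    if not (subjects - set(spec.test_subjects)):
        raise ValueError("training partition would be empty")
    train = [t for t in dataset.trials if t.subject_id not in spec.test_subjects]
    test = [t for t in dataset.trials if t.subject_id in spec.test_subjects]
    return train, test


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Percent correct: 100 x correct / total."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be non-empty and equal-length")
    return float(100.0 * np.mean(predictions == labels))


def confusion(
    predictions: np.ndarray, labels: np.ndarray, n_classes: int = 12
) -> np.ndarray:
    """Counts matrix: entry (i, j) = true class i+1 predicted as j+1."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("length mismatch")
    for arr, name in ((predictions, "prediction"), (labels, "label")):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} outside 1..{n_classes}")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (labels - 1, predictions - 1), 1)
    return mat


def qd(x: np.ndarray) -> float:
    """Quartile difference Q3 - Q1."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError("quartile difference needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75], method=QUARTILE_METHOD)
    return float(q3 - q1)


def md(x: np.ndarray) -> float:
    """Mean absolute deviation from the mean."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("mean deviation needs at least 2 values")
    return float(np.mean(np.abs(x - x.mean())))


def stdev(x: np.ndarray) -> float:
    """Sample standard deviation, sqrt(sum (x_i - mean)^2 / (n - 1))."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("standard deviation needs at least 2 values")
    return float(np.std(x, ddof=1))


def correlation_matrix(class_features: np.ndarray) -> np.ndarray:
    """Pearson correlation between class feature profiles.

    ``class_features`` is [n_classes x n_features]; any constant row makes
    the correlation undefined and raises.
    """
    x = np.atleast_2d(np.asarray(class_features, dtype=np.float64))
    if x.shape[1] < 2:
        raise ValueError("feature vectors need length >= 2")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant feature vector: correlation undefined")
    rho = np.corrcoef(x)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def five_number_summary(x: np.ndarray) -> dict:
    """Tukey box-plot statistics with 1.5 x IQR outlier fences."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 5:
        raise ValueError("five-number summary needs at least 5 values")
    q1, median, q3 = np.percentile(x, [25, 50, 75], method=QUARTILE_METHOD)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    inliers = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "min": float(inliers.min()),
        "q1": float(q1),
        "median": float(median),
        "q3": float(q3),
        "max": float(inliers.max()),
        "outliers": outliers.tolist(),
    }


@dataclass
class EvalReport:
    """Everything the experiment measures, plus how it was measured."""

    split_accuracies: list[float]
    confusion_matrix: np.ndarray
    class_stats: dict  # per-class qd/md/stdev of the mean feature profile
    correlation: np.ndarray
    box_summaries: list[dict]
    head_comparison: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.split_accuracies))

    def to_dict(self) -> dict:
        return {
            "split_accuracies": self.split_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_stats": self.class_stats,
            "correlation": self.correlation.tolist(),
            "box_summaries": self.box_summaries,
            "head_comparison": self.head_comparison,
            "metadata": self.metadata,
        }
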