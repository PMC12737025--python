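"""Classification metrics, confusion matrices, and robustness harnesses.

Per-class precision, recall and F1 follow the usual one-vs-rest
definitions; overall figures are support-weighted means over the classes
(weights n_i / sum n_i), which is what the grading pipeline reports.
Zero denominators yield 0 with a flag rather than NaN.

The module also houses the two robustness harnesses: named side-view
angle-combination presets for ablation runs, and the brightness sweep that
re-runs a pipeline under linear illumination scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "class_metrics",
    "ViewCombination",
    "view_presets",
    "get_preset",
    "run_view_ablation",
    "run_brightness_sweep",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = actual, columns = predicted, in `classes` order."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def supports(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=1)

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.counts), index=list(self.classes),
            columns=list(self.classes)
        ).rename_axis(index="Actual", columns="Predicted")


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class precision/recall/F1 plus support-weighted overall figures
    (proportions in [0, 1]; format as percent for display)."""

    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    supports: np.ndarray
    overall_precision: float
    overall_recall: float
    overall_f1: float
    zero_division_flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.supports,
            },
            index=list(self.classes),
        )


def confusion(
    actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Counts[i][j] = number of samples with actual class i predicted as j."""
    if len(actual) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted"
        )
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index:
            raise ValueError(f"unknown actual label {a!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class P_i, R_i, F1_i and their support-weighted overall means."""
    counts = np.asarray(cm.counts, dtype=float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    n = cm.supports.astype(float)

    flags = []
    precision = np.zeros(len(cm.classes))
    recall = np.zeros(len(cm.classes))
    f1 = np.zeros(len(cm.classes))
    for i, cls in enumerate(cm.classes):
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            flags.append(f"precision[{cls}]")
        if tp[i] + fn[i] > 0:
            recall[i] = tp[i] / (tp[i] + fn[i])
        else:
            flags.append(f"recall[{cls}]")
        if precision[i] + recall[i] > 0:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])
        else:
            flags.append(f"f1[{cls}]")

    total = n.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return ClassMetrics(
        classes=cm.classes,
        precision=precision,
        recall=recall,
        f1=f1,
        supports=cm.supports,
        overall_precision=float((n * precision).sum() / total),
        overall_recall=float((n * recall).sum() / total),
        overall_f1=float((n * f1).sum() / total),
        zero_division_flags=tuple(flags),
    )


@dataclass(frozen=True)
class ViewCombination:
    """A named subset of the eight side-view angles."""

    name: str
    angles: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.angles:
            raise ValueError(f"preset {self.name!r} has no angles")
        for a in self.angles:
            if a not in (0, 45, 90, 135, 180, 225, 270, 315):
                raise ValueError(f"invalid angle {a} in preset {self.name!r}")

    @property
    def excluded(self) -> tuple[int, ...]:
        return tuple(a for a in (0, 45, 90, 135, 180, 225, 270, 315)
                     if a not in self.angles)


def view_presets() -> dict[str, ViewCombination]:
    """The packaged registry of named angle combinations."""
    text = resources.files("phalgrade.data").joinpath("view_presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: ViewCombination(name, tuple(angles)) for name, angles in raw.items()
    }


def get_preset(name: str) -> ViewCombination:
    presets = view_presets()
    if name not in presets:
        raise KeyError(
            f"unknown view preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]


def run_view_ablation(
    dataset,
    combination: ViewCombination | str,
    run_pipeline: Callable[[object, tuple[int, ...]], tuple[list, list]],
) -> dict:
    """Run the grading pipeline restricted to one angle combination.

    ``run_pipeline(dataset, angles)`` must return (actual, predicted) grade
    lists — it owns whether models are retrained on the reduced views or
    reused with zero-padded features.  Returns the metrics plus a report of
    the included/excluded angles.
    """
    if isinstance(combination, str):
        combination = get_preset(combination)
    actual, predicted = run_pipeline(dataset, combination.angles)
    cm = confusion(actual, predicted, ("A", "B", "C"))
    m = class_metrics(cm)
    return {
        "preset": combination.name,
        "included_angles": combination.angles,
        "excluded_angles": combination.excluded,
        "confusion": cm,
        "metrics": m,
        "overall_f1": m.overall_f1,
    }


def run_brightness_sweep(
    dataset,
    alphas: Sequence[float],
    run_pipeline: Callable[[object, float], tuple[list, list]],
) -> pd.DataFrame:
    """Re-run the pipeline under each brightness coefficient alpha.

    ``run_pipeline(dataset, alpha)`` applies the linear brightness model to
    every input image, re-runs detection and grading, and returns (actual,
    predicted).  The report has one row per alpha, sorted ascending.
    """
    if any(a <= 0 for a in alphas):
        raise ValueError("brightness coefficients must be positive")
    rows = []
    for alpha in sorted(alphas):
        actual, predicted = run_pipeline(dataset, alpha)
        m = class_metrics(confusion(actual, predicted, ("A", "B", "C")))
        rows.append(
            {
                "alpha": alpha,
                "overall_precision": m.overall_precision,
                "overall_recall": m.overall_recall,
                "overall_f1": m.overall_f1,
            }
        )
    return pd.DataFrame(rows)
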