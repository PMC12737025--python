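"""Multi-view feature consolidation and the weighted defect score.

The eight side-view detection sets are consolidated into a fixed-schema
8 x 7 count matrix (view-major flattening gives the 56-d input of the
count-estimation stage), per-category total box areas A_i accumulated across
views, and the expert-weighted defect score S = sum_i w_i * A_i.  The final
quality classifier consumes a 17-d vector:

    [leaf-damage flag, shrinkage flag | 7 predicted counts |
     7 weighted areas w_i * A_i | root grade]

A defect seen from several adjacent views is counted once per view here —
deduplication is the job of the learned count model, not of feature
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detection import (
    DEFECT_CATEGORIES,
    SIDE_VIEW_ANGLES,
    DetectionSet,
    count_by_category,
)

__all__ = [
    "ScoreConfig",
    "TopViewFlags",
    "consolidate_defects",
    "flatten_matrix",
    "any_view_presence",
    "accumulate_areas",
    "weighted_score",
    "assemble_feature_vector",
    "top_view_flags",
    "FEATURE_NAMES",
]

N_CATEGORIES = len(DEFECT_CATEGORIES)  # 7
N_VIEWS = len(SIDE_VIEW_ANGLES)  # 8


@dataclass(frozen=True)
class ScoreConfig:
    """Per-category severity weights w_i for the defect score."""

    weights: tuple[float, ...] = (1.0,) * N_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.weights) != N_CATEGORIES:
            raise ValueError(
                f"need {N_CATEGORIES} weights, got {len(self.weights)}"
            )
        if any(w <= 0 for w in self.weights):
            raise ValueError(f"weights must be positive: {self.weights}")

    @property
    def k(self) -> int:
        return N_CATEGORIES


@dataclass(frozen=True)
class TopViewFlags:
    """Presence of the two top-view-detectable defects on the upper leaves."""

    leaf_damage_present: bool = False
    leaf_shrinkage_present: bool = False


def _views_of(per_view_sets: Mapping[int, DetectionSet] | Sequence[DetectionSet]):
    """Normalize input to {angle: DetectionSet}; reject duplicate views."""
    if isinstance(per_view_sets, Mapping):
        items = list(per_view_sets.items())
    else:
        items = [(s.view, s) for s in per_view_sets]
    seen: dict[int, DetectionSet] = {}
    for angle, dset in items:
        if angle not in SIDE_VIEW_ANGLES:
            raise ValueError(f"invalid side-view angle {angle!r}")
        if angle in seen:
            raise ValueError(f"duplicate view {angle}")
        seen[angle] = dset
    return seen


def consolidate_defects(
    per_view_sets: Mapping[int, DetectionSet] | Sequence[DetectionSet],
) -> np.ndarray:
    """8 x 7 matrix of per-view, per-category detection counts.

    Views absent from the input (e.g., under view ablation) contribute zero
    rows, keeping the downstream schema fixed at 56 features.
    """
    sets = _views_of(per_view_sets)
    matrix = np.zeros((N_VIEWS, N_CATEGORIES), dtype=int)
    for v, angle in enumerate(SIDE_VIEW_ANGLES):
        if angle in sets:
            matrix[v] = count_by_category(sets[angle])
    return matrix


def flatten_matrix(matrix: np.ndarray) -> np.ndarray:
    """View-major flattening to the 56-d stage-2 input."""
    matrix = np.asarray(matrix)
    if matrix.shape != (N_VIEWS, N_CATEGORIES):
        raise ValueError(f"expected {N_VIEWS}x{N_CATEGORIES} matrix, got {matrix.shape}")
    return matrix.reshape(-1)


def any_view_presence(matrix: np.ndarray) -> np.ndarray:
    """presence[c] is true iff any view detected category c at least once."""
    matrix = np.asarray(matrix)
    if matrix.shape != (N_VIEWS, N_CATEGORIES):
        raise ValueError(f"expected {N_VIEWS}x{N_CATEGORIES} matrix, got {matrix.shape}")
    return (matrix > 0).any(axis=0)


def accumulate_areas(
    per_view_sets: Mapping[int, DetectionSet] | Sequence[DetectionSet],
    *,
    normalized: bool = True,
) -> np.ndarray:
    """A_i: total predicted box area per category, summed across the views.

    Areas are in normalized image-area units by default, or pixels^2 when
    ``normalized=False`` (requires image_dims on every set).
    """
    sets = _views_of(per_view_sets)
    areas = np.zeros(N_CATEGORIES, dtype=float)
    for dset in sets.values():
        for det in dset:
            if det.category == "Flawless":
                continue
            i = DEFECT_CATEGORIES.index(det.category)
            if normalized:
                areas[i] += det.area_norm
            else:
                if dset.image_dims is None:
                    raise ValueError(
                        f"set {dset.image_id!r} has no image_dims; cannot "
                        "compute pixel areas"
                    )
                areas[i] += det.area_px(dset.image_dims)
    return areas


def weighted_score(areas: np.ndarray, cfg: ScoreConfig) -> float:
    """S = sum_i w_i * A_i."""
    areas = np.asarray(areas, dtype=float)
    if areas.shape != (N_CATEGORIES,):
        raise ValueError(f"expected {N_CATEGORIES} areas, got shape {areas.shape}")
    if (areas < 0).any():
        raise ValueError(f"negative area in {areas}")
    return float(np.dot(cfg.weights, areas))


FEATURE_NAMES: tuple[str, ...] = (
    ("top_leaf_damage", "top_leaf_shrinkage")
    + tuple(f"count_{c}" for c in DEFECT_CATEGORIES)
    + tuple(f"weighted_area_{c}" for c in DEFECT_CATEGORIES)
    + ("root_grade",)
)


def assemble_feature_vector(
    flags: TopViewFlags,
    counts: np.ndarray,
    areas: np.ndarray,
    cfg: ScoreConfig,
    root_grade: int,
) -> np.ndarray:
    """The 17-d quality-classifier input:
    [2 flags | 7 predicted counts | 7 weighted areas | root grade]."""
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if counts.shape != (N_CATEGORIES,):
        raise ValueError(f"expected {N_CATEGORIES} counts, got shape {counts.shape}")
    if areas.shape != (N_CATEGORIES,):
        raise ValueError(f"expected {N_CATEGORIES} areas, got shape {areas.shape}")
    if root_grade not in (1, 2, 3):
        raise ValueError(f"root grade must be 1, 2 or 3, got {root_grade}")
    weighted = np.asarray(cfg.weights) * areas
    return np.concatenate(
        [
            [float(flags.leaf_damage_present), float(flags.leaf_shrinkage_present)],
            counts,
            weighted,
            [float(root_grade)],
        ]
    )


def top_view_flags(top_set: DetectionSet) -> TopViewFlags:
    """Derive the two upper-leaf flags from the top-view detection set."""
    labels = {d.category for d in top_set}
    return TopViewFlags(
        leaf_damage_present="Leaf damage" in labels,
        leaf_shrinkage_present="Leaf shrinkage" in labels,
    )
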