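"""End-to-end harness: stage-1 outputs -> trained stage models -> grades.

Glue used by the CLI, the evaluation harnesses and the test suite: build
per-seedling detection bundles from synthetic states, assemble training
arrays, fit the three stage models, and grade whole datasets via either the
three-stage pipeline or the direct majority-vote method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import features as F
from .detection import SIDE_VIEW_ANGLES, DetectionSet
from .grading import (
    GradeResult,
    GradeThresholds,
    grade_direct,
    grade_three_stage,
    rule_based_grade,
    score_band_grade,
)
from .models import DefectCountSVR, QualityGradeSVC, RootGradeForest
from .root_rules import RuleSet, rule_grade, summarize_views
from .synthetic import (
    DEFAULT_THRESHOLDS,
    GeneratorConfig,
    SeedlingState,
    oracle_detection_bundle,
)

__all__ = [
    "SeedlingBundle",
    "build_bundles",
    "training_arrays",
    "fit_stage_models",
    "grade_bundle",
    "grade_all",
    "direct_votes",
]


@dataclass
class SeedlingBundle:
    """Stage-1 outputs for one seedling."""

    state: SeedlingState
    top_set: DetectionSet
    side_leaf_sets: dict[int, DetectionSet]
    side_root_sets: dict[int, DetectionSet]


def build_bundles(
    states: Sequence[SeedlingState],
    config: GeneratorConfig,
    *,
    views: Sequence[int] = SIDE_VIEW_ANGLES,
    seed: int | None = None,
) -> list[SeedlingBundle]:
    """Oracle stage-1 detections for every seedling, restricted to `views`."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bundles = []
    for state in states:
        top, leaf, root = oracle_detection_bundle(state, config, rng, views=views)
        bundles.append(SeedlingBundle(state, top, leaf, root))
    return bundles


def training_arrays(
    bundles: Sequence[SeedlingBundle],
    score_cfg: F.ScoreConfig | None = None,
) -> dict[str, np.ndarray]:
    """Feature/target arrays for the three stage models.

    Targets come from ground truth: per-category instance counts for the
    count model and rule-table root grades for the forest.
    """
    score_cfg = score_cfg or F.ScoreConfig()
    X56, Ycnt, Xroot, yroot, labels = [], [], [], [], []
    for b in bundles:
        X56.append(F.flatten_matrix(F.consolidate_defects(b.side_leaf_sets)))
        Ycnt.append(b.state.true_counts())
        rc = np.zeros(8, dtype=int)
        for v, angle in enumerate(SIDE_VIEW_ANGLES):
            if angle in b.side_root_sets:
                rc[v] = len(b.side_root_sets[angle])
        Xroot.append(rc)
        yroot.append(rule_grade(summarize_views(b.state.roots_per_view)))
        labels.append(b.state.true_grade)
    return {
        "X_counts": np.array(X56),
        "Y_counts": np.array(Ycnt),
        "X_root": np.array(Xroot),
        "y_root": np.array(yroot),
        "labels": np.array(labels),
    }


def fit_stage_models(
    bundles: Sequence[SeedlingBundle],
    *,
    score_cfg: F.ScoreConfig | None = None,
    seed: int = 42,
) -> dict:
    """Fit count SVRs, root forest and quality SVM on oracle bundles.

    The quality classifier is trained on the *predicted* counts and root
    grades of the fitted stage-2 models, so its inputs at train and predict
    time share the same distribution.
    """
    score_cfg = score_cfg or F.ScoreConfig()
    arrays = training_arrays(bundles, score_cfg)
    count_model = DefectCountSVR().fit(arrays["X_counts"], arrays["Y_counts"])
    root_model = RootGradeForest(random_state=seed).fit(
        arrays["X_root"], arrays["y_root"]
    )
    pred_counts = count_model.predict(arrays["X_counts"])
    pred_root = root_model.predict(arrays["X_root"])
    X17 = []
    for i, b in enumerate(bundles):
        flags = F.top_view_flags(b.top_set)
        areas = F.accumulate_areas(b.side_leaf_sets)
        X17.append(
            F.assemble_feature_vector(
                flags, pred_counts[i], areas, score_cfg, int(pred_root[i])
            )
        )
    quality_model = QualityGradeSVC(random_state=seed).fit(
        np.array(X17), arrays["labels"]
    )
    return {"count": count_model, "root": root_model, "quality": quality_model}


def grade_bundle(
    bundle: SeedlingBundle,
    models: Mapping | None = None,
    *,
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
    score_cfg: F.ScoreConfig | None = None,
    rules: RuleSet | None = None,
    policy: str = "worse_of",
) -> GradeResult:
    """Three-stage grade for one bundle; with ``models=None`` every learned
    stage is replaced by its deterministic rule-based substitute."""
    models = models or {}
    return grade_three_stage(
        bundle.top_set,
        bundle.side_leaf_sets,
        bundle.side_root_sets,
        thresholds=thresholds,
        score_cfg=score_cfg,
        count_model=models.get("count"),
        root_model=models.get("root"),
        quality_model=models.get("quality"),
        rules=rules,
        policy=policy,
    )


def grade_all(
    bundles: Sequence[SeedlingBundle],
    models: Mapping | None = None,
    **kw,
) -> list[GradeResult]:
    return [grade_bundle(b, models, **kw) for b in bundles]


def direct_votes(
    bundle: SeedlingBundle,
    *,
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
    score_cfg: F.ScoreConfig | None = None,
) -> GradeResult:
    """Direct method on oracle outputs: one rule-derived grade vote per
    image (top + each side view), combined by majority voting.

    Each side image votes the worse of its per-image score band (thresholds
    scaled down to single-view scale by the number of views) and its root
    bin (>=3 roots -> A, 2 -> B, <=1 -> C).  The top image votes by its
    defect flags.
    """
    score_cfg = score_cfg or F.ScoreConfig()
    n_views = max(len(bundle.side_leaf_sets), 1)
    per_view_th = GradeThresholds(
        thresholds.T_A / n_views, thresholds.T_C / n_views
    )
    side_votes = []
    for angle, leaf_set in bundle.side_leaf_sets.items():
        areas = F.accumulate_areas({angle: leaf_set})
        s_grade = score_band_grade(F.weighted_score(areas, score_cfg), per_view_th)
        n_roots = len(bundle.side_root_sets.get(angle, ()))
        root_vote = "A" if n_roots >= 3 else ("B" if n_roots == 2 else "C")
        side_votes.append(max(s_grade, root_vote))  # lexicographic: C worst
    flags = F.top_view_flags(bundle.top_set)
    top_vote = "B" if (flags.leaf_damage_present or flags.leaf_shrinkage_present) else "A"
    result = grade_direct(top_vote, side_votes)
    result.provenance["top_vote"] = top_vote
    result.provenance["side_votes"] = side_votes
    return result
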