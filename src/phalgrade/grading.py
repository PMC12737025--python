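"""Grade combination rules, threshold calibration, and the two grading
pipelines.

Two routes produce the final A/B/C quality grade:

* the interpretable three-stage pipeline — detect per image, consolidate
  into counts/areas/root grade, then classify the 17-d feature vector (or,
  in rule mode, combine the weighted defect score S with the root grade G
  directly); and
* the direct method — one grade vote per image (top + up to eight side
  views) combined by majority voting.

The score bands are half-open: S < T_A is the A band, T_A <= S < T_C the B
band, S >= T_C the C band.  The root grade maps G=3 -> A, G=2 -> B,
G=1 -> C.  Because the two channels can disagree, a combination policy
resolves them; the default takes the worse of the two grades, the
risk-averse choice for commercial inspection where calling a poor seedling
healthy is the costliest error.  Majority-vote ties likewise break toward
the worse grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import features as F
from .detection import DetectionSet, count_by_category
from .metrics import class_metrics, confusion
from .root_rules import RuleSet, rule_grade, summarize_views

__all__ = [
    "GRADES",
    "GradeThresholds",
    "GradeResult",
    "score_band_grade",
    "root_grade_to_quality",
    "rule_based_grade",
    "calibrate_thresholds",
    "grade_direct",
    "grade_three_stage",
]

#: Quality grades ordered best to worst.
GRADES: tuple[str, ...] = ("A", "B", "C")
_WORSE = {g: i for i, g in enumerate(GRADES)}  # larger index = worse

CombinePolicy = Literal["worse_of", "score_priority", "root_priority"]


@dataclass(frozen=True)
class GradeThresholds:
    """Score cut points: S < T_A -> A band, T_A <= S < T_C -> B, S >= T_C -> C."""

    T_A: float
    T_C: float

    def __post_init__(self) -> None:
        if not (0 <= self.T_A < self.T_C):
            raise ValueError(
                f"thresholds must satisfy 0 <= T_A < T_C, got {self}"
            )


@dataclass
class GradeResult:
    """Final grade plus per-stage provenance for auditability."""

    grade: str
    method: str
    provenance: dict = field(default_factory=dict)


def score_band_grade(S: float, th: GradeThresholds) -> str:
    if S < 0:
        raise ValueError(f"score must be nonnegative, got {S}")
    if S < th.T_A:
        return "A"
    if S < th.T_C:
        return "B"
    return "C"


def root_grade_to_quality(G: int) -> str:
    try:
        return {3: "A", 2: "B", 1: "C"}[int(G)]
    except KeyError:
        raise ValueError(f"root grade must be 1, 2 or 3, got {G}") from None


def rule_based_grade(
    S: float,
    G: int,
    th: GradeThresholds,
    policy: CombinePolicy = "worse_of",
) -> str:
    """Combine the weighted defect score and the root grade into A/B/C."""
    s_grade = score_band_grade(S, th)
    g_grade = root_grade_to_quality(G)
    if policy == "score_priority":
        return s_grade
    if policy == "root_priority":
        return g_grade
    return s_grade if _WORSE[s_grade] >= _WORSE[g_grade] else g_grade


def calibrate_thresholds(
    scores: Sequence[float],
    root_grades: Sequence[int],
    labels: Sequence[str],
    *,
    folds: int = 5,
    n_grid: int = 25,
    policy: CombinePolicy = "worse_of",
    seed: int = 0,
) -> GradeThresholds:
    """Grid-search (T_A, T_C) over score quantiles, maximizing the mean
    cross-validated weighted F1 of :func:`rule_based_grade`.

    Ties break toward the larger A band (larger T_A, then larger T_C).
    Grid points with T_A >= T_C are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    root_grades = np.asarray(root_grades, dtype=int)
    labels = np.asarray(labels)
    if not (len(scores) == len(root_grades) == len(labels)):
        raise ValueError("scores, root_grades and labels must have equal length")
    if len(scores) < 30:
        raise ValueError(f"need at least 30 labeled samples, got {len(scores)}")
    if set(labels) != set(GRADES):
        raise ValueError(f"all grades {GRADES} must be present, got {set(labels)}")

    qs = np.linspace(0.02, 0.98, n_grid)
    candidates = np.unique(np.quantile(scores, qs))
    positive = candidates[candidates > 0]
    pairs = [
        (float(ta), float(tc))
        for i, ta in enumerate(positive)
        for tc in positive[i + 1:]
    ]
    if not pairs:
        raise ValueError("no valid (T_A, T_C) grid points with T_A < T_C")
    if len(pairs) == 1:
        return GradeThresholds(*pairs[0])

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(scores, labels))

    def cv_f1(ta: float, tc: float) -> float:
        th = GradeThresholds(ta, tc)
        f1s = []
        for _, test_idx in splits:
            pred = [
                rule_based_grade(scores[i], root_grades[i], th, policy)
                for i in test_idx
            ]
            cm = confusion(labels[test_idx], pred, GRADES)
            f1s.append(class_metrics(cm).overall_f1)
        return float(np.mean(f1s))

    # Tie-break toward the larger A band: evaluate larger T_A (then T_C)
    # first and replace only on strict improvement.
    best, best_f1 = None, -1.0
    for ta, tc in sorted(pairs, reverse=True):
        f1 = cv_f1(ta, tc)
        if f1 > best_f1 + 1e-12:
            best, best_f1 = (ta, tc), f1
    return GradeThresholds(*best)


def grade_direct(
    top_grade_vote: str | None,
    side_grade_votes: Sequence[str],
) -> GradeResult:
    """Majority vote over per-image grades; ties break toward the worse
    grade.  Missing views simply contribute no vote."""
    votes = list(side_grade_votes)
    if top_grade_vote is not None:
        votes.append(top_grade_vote)
    if not votes:
        raise ValueError("no votes: at least one per-image grade is required")
    for v in votes:
        if v not in GRADES:
            raise ValueError(f"invalid grade vote {v!r}")
    tally = {g: votes.count(g) for g in GRADES}
    top_count = max(tally.values())
    winners = [g for g in GRADES if tally[g] == top_count]
    grade = max(winners, key=lambda g: _WORSE[g])  # tie -> worse
    return GradeResult(
        grade=grade,
        method="direct",
        provenance={"votes": tally, "n_votes": len(votes), "tie": len(winners) > 1},
    )


def grade_three_stage(
    top_set: DetectionSet,
    side_leaf_sets: Mapping[int, DetectionSet],
    side_root_sets: Mapping[int, DetectionSet],
    *,
    thresholds: GradeThresholds,
    score_cfg: F.ScoreConfig | None = None,
    count_model=None,
    root_model=None,
    quality_model=None,
    rules: RuleSet | None = None,
    policy: CombinePolicy = "worse_of",
) -> GradeResult:
    """Run stages 2-3 on per-image detection sets (stage-1 outputs).

    Stage 2 estimates per-category defect counts (the trained count model,
    or raw column sums in rule mode) and a root grade (the trained forest,
    or the deterministic rule table when ``root_model`` is None).  Stage 3
    classifies the assembled 17-d feature vector with the quality model, or
    combines S and G by :func:`rule_based_grade` when ``quality_model`` is
    None.  The provenance records every intermediate quantity.
    """
    if top_set is None:
        raise ValueError("the three-stage method requires the top view")
    score_cfg = score_cfg or F.ScoreConfig()

    matrix = F.consolidate_defects(side_leaf_sets)
    areas = F.accumulate_areas(side_leaf_sets)
    S = F.weighted_score(areas, score_cfg)
    flags = F.top_view_flags(top_set)

    root_counts = np.zeros(8, dtype=int)
    for v, angle in enumerate(F.SIDE_VIEW_ANGLES):
        if angle in side_root_sets:
            root_counts[v] = len(side_root_sets[angle])

    if root_model is not None:
        G = int(root_model.predict(root_counts.reshape(1, -1))[0])
        root_source = "forest"
    else:
        G = rule_grade(summarize_views(root_counts), rules)
        root_source = "rules"

    if count_model is not None:
        counts = np.asarray(count_model.predict(F.flatten_matrix(matrix).reshape(1, -1))[0])
        count_source = "svr"
    else:
        counts = matrix.sum(axis=0).astype(float)
        count_source = "column_sums"

    x = F.assemble_feature_vector(flags, counts, areas, score_cfg, G)
    if quality_model is not None:
        grade = str(quality_model.predict(x.reshape(1, -1))[0])
        stage3 = "svm"
    else:
        grade = rule_based_grade(S, G, thresholds, policy)
        stage3 = "rules"

    return GradeResult(
        grade=grade,
        method="three-stage",
        provenance={
            "top_flags": (flags.leaf_damage_present, flags.leaf_shrinkage_present),
            "count_matrix": matrix,
            "predicted_counts": counts,
            "areas": areas,
            "S": S,
            "root_counts": root_counts,
            "root_grade": G,
            "root_source": root_source,
            "count_source": count_source,
            "stage3": stage3,
            "feature_vector": x,
        },
    )
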