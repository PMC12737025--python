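"""Ground-truthed synthetic seedlings for end-to-end pipeline testing.

Every downstream stage of the grading pipeline is exercised against
procedurally generated moth-orchid seedlings: a sampled ground-truth state
(defect instances, per-view root counts, top-view flags, true grade),
schematic rendered images, and noise-controlled detector outputs.

A defect instance lives on the plant and is therefore visible from a
contiguous arc of side views — the same lesion is re-detected from adjacent
turntable angles, which is exactly the multi-view duplication the count
model must learn to undo.  The true per-category defect count is the number
of instances, not the number of per-view detections.

Rendering is deliberately schematic (leaf ellipses, lesion blobs, root
strokes on a white background): the acceptance surface of this package is
pipeline logic, not detector training, so photorealism is a non-goal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from skimage import draw

from .detection import (
    DEFECT_CATEGORIES,
    ROOT_SCHEME,
    SIDE_SCHEME,
    SIDE_VIEW_ANGLES,
    TOP_SCHEME,
    Detection,
    DetectionSet,
    write_yolo_annotations,
)
from .features import ScoreConfig
from .grading import GradeThresholds, rule_based_grade
from .root_rules import RuleSet, rule_grade, summarize_views

__all__ = [
    "DefectInstance",
    "SeedlingState",
    "GeneratorConfig",
    "DEFAULT_THRESHOLDS",
    "generate_seedling_state",
    "derive_true_grade",
    "emit_detections",
    "oracle_detection_bundle",
    "render_top_view",
    "render_side_view",
    "OracleDetector",
    "write_dataset",
]

#: Default score cut points in normalized image-area units (the generator's
#: lesion sizes are fractions of the side-view image area).
DEFAULT_THRESHOLDS = GradeThresholds(T_A=0.005, T_C=0.03)

DetectionKind = Literal["side-leaf", "side-root", "top"]


@dataclass(frozen=True)
class DefectInstance:
    """One physical lesion: category, normalized area, the contiguous arc of
    side views it is visible from, and its (shared) box center."""

    category: str
    size: float
    visible_views: frozenset[int]
    on_upper_leaf: bool
    cx: float = 0.5
    cy: float = 0.4

    def __post_init__(self) -> None:
        if self.category not in DEFECT_CATEGORIES:
            raise ValueError(f"unknown defect category {self.category!r}")
        if not self.size > 0:
            raise ValueError(f"size must be positive, got {self.size}")
        if not self.visible_views:
            raise ValueError("visible_views must be non-empty")
        if not self.visible_views <= set(SIDE_VIEW_ANGLES):
            raise ValueError(f"invalid view angles {self.visible_views}")
        if not _is_contiguous_arc(self.visible_views):
            raise ValueError(
                f"visible_views {sorted(self.visible_views)} is not a "
                "contiguous arc on the 8-view circle"
            )


def _is_contiguous_arc(views: frozenset[int]) -> bool:
    idx = sorted(SIDE_VIEW_ANGLES.index(v) for v in views)
    n = len(idx)
    if n == 8:
        return True
    # contiguous iff some rotation makes the indices consecutive
    for start in idx:
        if all((start + k) % 8 in idx for k in range(n)):
            return True
    return False


@dataclass(frozen=True)
class SeedlingState:
    """Complete ground truth for one synthetic seedling."""

    seedling_id: str
    defects: tuple[DefectInstance, ...]
    roots_per_view: tuple[int, ...]
    top_leaf_damage: bool
    top_leaf_shrinkage: bool
    true_grade: str

    def __post_init__(self) -> None:
        if len(self.roots_per_view) != 8:
            raise ValueError(
                f"roots_per_view needs 8 entries, got {len(self.roots_per_view)}"
            )
        if any(r < 0 for r in self.roots_per_view):
            raise ValueError("root counts must be nonnegative")
        if self.true_grade not in ("A", "B", "C"):
            raise ValueError(f"invalid grade {self.true_grade!r}")

    def true_counts(self) -> np.ndarray:
        """Per-category number of defect instances (multi-view duplication
        removed)."""
        counts = np.zeros(len(DEFECT_CATEGORIES), dtype=int)
        for d in self.defects:
            counts[DEFECT_CATEGORIES.index(d.category)] += 1
        return counts

    def true_areas(self, views: Sequence[int] = SIDE_VIEW_ANGLES) -> np.ndarray:
        """Per-category total detected area integrated over the given views:
        each instance contributes its size once per view it is visible from
        (what a perfect detector would accumulate)."""
        areas = np.zeros(len(DEFECT_CATEGORIES), dtype=float)
        for d in self.defects:
            n_vis = len(d.visible_views & set(views))
            areas[DEFECT_CATEGORIES.index(d.category)] += d.size * n_vis
        return areas


_DISTRIBUTIONS = {"poisson", "constant", "uniform_int"}


def _draw_count(rng: np.random.Generator, dist: tuple[str, dict], fieldname: str) -> int:
    name, params = dist
    try:
        if name == "poisson":
            lam = float(params["lam"])
            if lam < 0:
                raise ValueError("lam must be >= 0")
            return int(rng.poisson(lam))
        if name == "constant":
            v = int(params["value"])
            if v < 0:
                raise ValueError("value must be >= 0")
            return v
        if name == "uniform_int":
            lo, hi = int(params["low"]), int(params["high"])
            if not 0 <= lo <= hi:
                raise ValueError("need 0 <= low <= high")
            return int(rng.integers(lo, hi + 1))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid {fieldname} {dist!r}: {exc}") from None
    raise ValueError(
        f"invalid {fieldname}: unknown distribution {name!r} "
        f"(supported: {sorted(_DISTRIBUTIONS)})"
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic population.

    Defaults emulate a commercial incoming-inspection batch: roughly a fifth
    of seedlings defect-free (count ~ Poisson(1.5)), lesion areas lognormal
    in normalized image-area units, each lesion visible from 1-4 consecutive
    views, and vigorous-but-variable roots (per-view count ~ Poisson(5)).
    """

    category_prevalence: tuple[float, ...] = (1 / 7,) * 7
    defect_count_distribution: tuple[str, dict] = ("poisson", {"lam": 1.5})
    view_span_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}
    )
    root_distribution: tuple[str, dict] = ("poisson", {"lam": 5.0})
    size_log_mean: float = -5.5  # median lesion area ~ 0.4% of image area
    size_log_sigma: float = 0.8
    p_upper_leaf: float = 0.5
    detector_miss_rate: float = 0.0
    detector_false_positive_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.category_prevalence) != 7:
            raise ValueError(
                "invalid category_prevalence: need 7 entries, got "
                f"{len(self.category_prevalence)}"
            )
        if any(not 0 <= p <= 1 for p in self.category_prevalence):
            raise ValueError(
                f"invalid category_prevalence: entries outside [0,1]: "
                f"{self.category_prevalence}"
            )
        spans = self.view_span_distribution
        if not spans or any(not 1 <= s <= 8 for s in spans):
            raise ValueError(
                f"invalid view_span_distribution: spans must be 1-8, got {spans}"
            )
        if any(p < 0 for p in spans.values()) or sum(spans.values()) <= 0:
            raise ValueError(
                f"invalid view_span_distribution: bad probabilities {spans}"
            )
        for name in ("detector_miss_rate",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"invalid {name}: {v} outside [0,1]")
        if self.detector_false_positive_rate < 0:
            raise ValueError(
                f"invalid detector_false_positive_rate: "
                f"{self.detector_false_positive_rate} < 0"
            )
        # validate count distributions eagerly so errors name the field
        probe = np.random.default_rng(0)
        _draw_count(probe, self.defect_count_distribution, "defect_count_distribution")
        _draw_count(probe, self.root_distribution, "root_distribution")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def derive_true_grade(
    state_or_parts,
    score_config: ScoreConfig | None = None,
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
    *,
    rules: RuleSet | None = None,
    policy: str = "worse_of",
) -> str:
    """Ground-truth grade: the rule-based combiner applied to the state's
    true integrated areas and its rule-derived root grade."""
    state = state_or_parts
    score_config = score_config or ScoreConfig()
    S = float(np.dot(score_config.weights, state.true_areas()))
    G = rule_grade(summarize_views(state.roots_per_view), rules)
    return rule_based_grade(S, G, thresholds, policy)


def generate_seedling_state(
    config: GeneratorConfig,
    n: int,
    *,
    score_config: ScoreConfig | None = None,
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
) -> list[SeedlingState]:
    """Sample n ground-truth seedlings; bit-reproducible under the config
    seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = config.rng()
    prev = np.asarray(config.category_prevalence, dtype=float)
    spans = sorted(config.view_span_distribution.items())
    span_vals = np.array([s for s, _ in spans])
    span_p = np.array([p for _, p in spans], dtype=float)
    span_p /= span_p.sum()

    states = []
    for i in range(n):
        n_defects = _draw_count(
            rng, config.defect_count_distribution, "defect_count_distribution"
        )
        defects = []
        for _ in range(n_defects):
            if prev.sum() <= 0:
                break  # all prevalences zero: no defects can occur
            p = prev / prev.sum()
            cat = DEFECT_CATEGORIES[int(rng.choice(7, p=p))]
            size = float(
                np.clip(
                    rng.lognormal(config.size_log_mean, config.size_log_sigma),
                    5e-4,
                    0.05,
                )
            )
            span = int(rng.choice(span_vals, p=span_p))
            start = int(rng.integers(0, 8))
            views = frozenset(
                SIDE_VIEW_ANGLES[(start + k) % 8] for k in range(span)
            )
            side = np.sqrt(size)
            cx = float(rng.uniform(0.25, 0.75))
            cy = float(rng.uniform(0.2, 0.6))
            cx = float(np.clip(cx, side / 2, 1 - side / 2))
            cy = float(np.clip(cy, side / 2, 1 - side / 2))
            defects.append(
                DefectInstance(
                    category=cat,
                    size=size,
                    visible_views=views,
                    on_upper_leaf=bool(rng.random() < config.p_upper_leaf),
                    cx=cx,
                    cy=cy,
                )
            )
        roots = tuple(
            _draw_count(rng, config.root_distribution, "root_distribution")
            for _ in range(8)
        )
        damage = any(
            d.category == "Leaf damage" and d.on_upper_leaf for d in defects
        )
        shrink = any(
            d.category == "Leaf shrinkage" and d.on_upper_leaf for d in defects
        )
        partial = SeedlingState(
            seedling_id=f"seedling-{i:04d}",
            defects=tuple(defects),
            roots_per_view=roots,
            top_leaf_damage=damage,
            top_leaf_shrinkage=shrink,
            true_grade="A",  # placeholder, replaced below
        )
        grade = derive_true_grade(partial, score_config, thresholds)
        states.append(dataclasses.replace(partial, true_grade=grade))
    return states


def _noisy(
    detections: list[Detection],
    config: GeneratorConfig,
    rng: np.random.Generator,
    scheme,
) -> list[Detection]:
    """Independent per-detection misses plus Poisson spurious boxes."""
    out = []
    for det in detections:
        if config.detector_miss_rate > 0 and rng.random() < config.detector_miss_rate:
            continue
        out.append(det)
    n_fp = (
        int(rng.poisson(config.detector_false_positive_rate))
        if config.detector_false_positive_rate > 0
        else 0
    )
    fp_labels = [lab for lab in scheme.labels if lab != "Flawless"]
    for _ in range(n_fp):
        w = h = float(rng.uniform(0.02, 0.08))
        out.append(
            Detection(
                category=fp_labels[int(rng.integers(len(fp_labels)))],
                cx=float(rng.uniform(w / 2, 1 - w / 2)),
                cy=float(rng.uniform(h / 2, 1 - h / 2)),
                w=w,
                h=h,
                confidence=float(rng.uniform(0.3, 0.9)),
            )
        )
    return out


def emit_detections(
    state: SeedlingState,
    view: int | str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    kind: DetectionKind = "side-leaf",
) -> DetectionSet:
    """Synthetic stage-1 output for one image.

    With zero noise rates the set contains exactly one detection per defect
    instance visible from the view (or per visible root in root mode, or per
    raised top-view flag); nonzero rates drop instances / add spurious boxes
    by independent draws from ``rng``.
    """
    if kind == "top" and view != "top":
        raise ValueError("top detections require view='top'")
    if kind != "top" and view not in SIDE_VIEW_ANGLES:
        raise ValueError(f"side detections require a side-view angle, got {view!r}")

    if kind == "side-leaf":
        scheme = SIDE_SCHEME
        base = [
            Detection(d.category, d.cx, d.cy, np.sqrt(d.size), np.sqrt(d.size))
            for d in state.defects
            if view in d.visible_views
        ]
    elif kind == "side-root":
        scheme = ROOT_SCHEME
        n_roots = state.roots_per_view[SIDE_VIEW_ANGLES.index(view)]
        base = [
            Detection("Root", 0.1 + 0.8 * (j + 0.5) / max(n_roots, 1), 0.85,
                      0.03, 0.12)
            for j in range(n_roots)
        ]
    elif kind == "top":
        scheme = TOP_SCHEME
        base = []
        if state.top_leaf_damage:
            base.append(Detection("Leaf damage", 0.4, 0.35, 0.08, 0.08))
        if state.top_leaf_shrinkage:
            base.append(Detection("Leaf shrinkage", 0.6, 0.55, 0.1, 0.1))
    else:
        raise ValueError(f"unknown detection kind {kind!r}")

    return DetectionSet(
        image_id=f"{state.seedling_id}_{view}",
        view=view,
        scheme=scheme,
        detections=_noisy(base, config, rng, scheme),
    )


def oracle_detection_bundle(
    state: SeedlingState,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    *,
    views: Sequence[int] = SIDE_VIEW_ANGLES,
) -> tuple[DetectionSet, dict[int, DetectionSet], dict[int, DetectionSet]]:
    """All stage-1 outputs for one seedling: (top set, side leaf sets, side
    root sets), restricted to the given side views."""
    rng = rng if rng is not None else config.rng()
    top = emit_detections(state, "top", config, rng, kind="top")
    leaf = {
        v: emit_detections(state, v, config, rng, kind="side-leaf") for v in views
    }
    root = {
        v: emit_detections(state, v, config, rng, kind="side-root") for v in views
    }
    return top, leaf, root


# ---------------------------------------------------------------------------
# schematic rendering

_BG = 255
_LOWER_LEAF = (46, 112, 51)
_UPPER_LEAF = (74, 154, 74)
_LESION = (123, 74, 34)
_POT = (164, 121, 80)
_ROOT = (206, 212, 180)


def render_top_view(
    state: SeedlingState, size: tuple[int, int] = (640, 480)
) -> tuple[np.ndarray, np.ndarray]:
    """Schematic top view: (RGB, depth) images of `size` = (width, height).

    Two lower-leaf ellipses (left/right) and two upper-leaf ellipses
    (up/down) on a white background.  The depth image encodes layering —
    upper leaves nearer (higher value), background 0.  Upper-leaf lesions
    are drawn as blobs; shrinkage shortens the upper leaves below the lower
    leaves' extent.
    """
    w, h = size
    rgb = np.full((h, w, 3), _BG, dtype=np.uint8)
    depth = np.zeros((h, w), dtype=np.uint8)
    cx, cy = w // 2, h // 2

    lower_len = int(0.42 * min(w, h))
    upper_len = (
        int(0.62 * lower_len) if state.top_leaf_shrinkage else int(1.08 * lower_len)
    )
    upper_len = min(upper_len, cy - 2, cx - 2)

    # lower leaves along the horizontal axis
    for direction in (-1, 1):
        rr, cc = draw.ellipse(
            cy, cx + direction * lower_len // 2, lower_len // 4, lower_len // 2,
            shape=(h, w),
        )
        rgb[rr, cc] = _LOWER_LEAF
        depth[rr, cc] = 100
    # upper leaves along the vertical axis, drawn on top (nearer)
    for direction in (-1, 1):
        rr, cc = draw.ellipse(
            cy + direction * upper_len // 2, cx, upper_len // 2, upper_len // 4,
            shape=(h, w),
        )
        rgb[rr, cc] = _UPPER_LEAF
        depth[rr, cc] = 200

    for d in state.defects:
        if not d.on_upper_leaf:
            continue
        r = max(2, int(np.sqrt(d.size) * min(w, h) / 2))
        # place lesions along the upper-leaf axis so they land on leaf pixels
        t = (d.cx - 0.5) * 1.2
        rr, cc = draw.disk(
            (int(cy + t * upper_len * 0.8), cx), r, shape=(h, w)
        )
        on_leaf = depth[rr, cc] > 0
        rgb[rr[on_leaf], cc[on_leaf]] = _LESION
    return rgb, depth


def render_side_view(
    state: SeedlingState, view: int, size: tuple[int, int] = (640, 480)
) -> np.ndarray:
    """Schematic side view: leaves above, pot and visible roots below."""
    if view not in SIDE_VIEW_ANGLES:
        raise ValueError(f"invalid side view {view!r}")
    w, h = size
    rgb = np.full((h, w, 3), _BG, dtype=np.uint8)
    # pot
    rr, cc = draw.rectangle(
        (int(0.72 * h), int(0.3 * w)), end=(h - 1, int(0.7 * w)), shape=(h, w)
    )
    rgb[rr, cc] = _POT
    # leaf fan
    for k, direction in enumerate((-1, 1, -1, 1)):
        rr, cc = draw.ellipse(
            int(0.45 * h), int(w / 2 + direction * (0.08 + 0.05 * k) * w),
            int(0.18 * h), int(0.1 * w), shape=(h, w),
        )
        rgb[rr, cc] = _LOWER_LEAF if k < 2 else _UPPER_LEAF
    # visible roots as strokes over the pot
    n_roots = state.roots_per_view[SIDE_VIEW_ANGLES.index(view)]
    for j in range(n_roots):
        x = int(0.32 * w + 0.36 * w * (j + 0.5) / max(n_roots, 1))
        rr, cc = draw.rectangle(
            (int(0.74 * h), x - 2), end=(int(0.95 * h), x + 2), shape=(h, w)
        )
        rgb[rr, cc] = _ROOT
    # lesions visible from this view
    for d in state.defects:
        if view not in d.visible_views:
            continue
        r = max(2, int(np.sqrt(d.size) * min(w, h) / 2))
        rr, cc = draw.disk((int(d.cy * h * 0.7 + 0.1 * h), int(d.cx * w)), r,
                           shape=(h, w))
        rgb[rr, cc] = _LESION
    return rgb


class OracleDetector:
    """Detector-contract implementation backed by ground-truth states.

    Ignores pixel content by default (it reads the truth), but an optional
    minimum mean-intensity gate makes it brightness-sensitive for the
    lighting-robustness harness: images darker than ``min_mean_intensity``
    yield no detections, emulating a detector failing in underexposure.
    """

    def __init__(
        self,
        states: Mapping[str, SeedlingState],
        kind: DetectionKind,
        config: GeneratorConfig | None = None,
        *,
        seed: int = 0,
        min_mean_intensity: float | None = None,
    ):
        self.states = dict(states)
        self.kind = kind
        self.config = config or GeneratorConfig(
            detector_miss_rate=0.0, detector_false_positive_rate=0.0
        )
        self.rng = np.random.default_rng(seed)
        self.min_mean_intensity = min_mean_intensity
        self.scheme = {"side-leaf": SIDE_SCHEME, "side-root": ROOT_SCHEME,
                       "top": TOP_SCHEME}[kind]

    def detect(self, image, *, image_id: str, view) -> DetectionSet:
        state = self.states[image_id]
        if (
            self.min_mean_intensity is not None
            and image is not None
            and float(np.mean(image)) < self.min_mean_intensity
        ):
            return DetectionSet(
                image_id=f"{state.seedling_id}_{view}", view=view,
                scheme=self.scheme,
            )
        return emit_detections(state, view, self.config, self.rng, kind=self.kind)


def write_dataset(
    out_dir: str | Path,
    states: Sequence[SeedlingState],
    config: GeneratorConfig,
    *,
    render: bool = True,
    side_size: tuple[int, int] = (640, 480),
) -> dict:
    """Write a full synthetic dataset: PNG images, per-image annotation
    files, a ground-truth JSON sidecar per seedling, and a manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    rng = config.rng()
    manifest = {"seed": config.seed, "n": len(states), "seedlings": []}
    for state in states:
        entry = {"id": state.seedling_id, "grade": state.true_grade, "images": []}
        if render:
            rgb, depth = render_top_view(state)
            iio.imwrite(out / "images" / f"{state.seedling_id}_top.png", rgb)
            iio.imwrite(
                out / "images" / f"{state.seedling_id}_top_depth.png",
                depth.astype(np.uint16) * 257,  # 16-bit depth PNG
            )
            entry["images"].append(f"{state.seedling_id}_top.png")
        top = emit_detections(state, "top", config, rng, kind="top")
        write_yolo_annotations(top, out / "labels" / f"{state.seedling_id}_top.txt")
        for v in SIDE_VIEW_ANGLES:
            if render:
                side = render_side_view(state, v, side_size)
                iio.imwrite(out / "images" / f"{state.seedling_id}_{v}.png", side)
                entry["images"].append(f"{state.seedling_id}_{v}.png")
            leaf = emit_detections(state, v, config, rng, kind="side-leaf")
            root = emit_detections(state, v, config, rng, kind="side-root")
            write_yolo_annotations(
                leaf, out / "labels" / f"{state.seedling_id}_{v}_leaf.txt"
            )
            write_yolo_annotations(
                root, out / "labels" / f"{state.seedling_id}_{v}_root.txt"
            )
        truth = {
            "id": state.seedling_id,
            "true_grade": state.true_grade,
            "roots_per_view": list(state.roots_per_view),
            "top_leaf_damage": state.top_leaf_damage,
            "top_leaf_shrinkage": state.top_leaf_shrinkage,
            "defects": [
                {
                    "category": d.category,
                    "size": d.size,
                    "visible_views": sorted(d.visible_views),
                    "on_upper_leaf": d.on_upper_leaf,
                    "cx": d.cx,
                    "cy": d.cy,
                }
                for d in state.defects
            ],
        }
        (out / "truth" / f"{state.seedling_id}.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True)
        )
        manifest["seedlings"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
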