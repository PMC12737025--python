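"""Synthetic seedling generation, rendering, and oracle detections."""

import dataclasses
import json

import numpy as np
import pytest

from phalgrade.detection import SIDE_VIEW_ANGLES
from phalgrade.features import ScoreConfig
from phalgrade.grading import GradeThresholds
from phalgrade.synthetic import (
    DEFAULT_THRESHOLDS,
    DefectInstance,
    GeneratorConfig,
    SeedlingState,
    derive_true_grade,
    emit_detections,
    generate_seedling_state,
    render_side_view,
    render_top_view,
    write_dataset,
)


def _state(defects=(), roots=(5,) * 8, damage=False, shrink=False, grade="A"):
    return SeedlingState("s0", tuple(defects), tuple(roots), damage, shrink, grade)


def _defect(category="Disease", size=0.01, views=(0,), upper=False, cx=0.5, cy=0.4):
    return DefectInstance(category, size, frozenset(views), upper, cx, cy)


class TestStateValidation:
    def test_visible_views_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            _defect(views=(0, 90))  # 45 missing between them

    def test_wraparound_arc_accepted(self):
        _defect(views=(315, 0, 45))  # arc across the 0-degree seam

    def test_full_circle_accepted(self):
        _defect(views=SIDE_VIEW_ANGLES)

    def test_empty_views_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            _defect(views=())

    def test_bad_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            _defect(category="Rust")

    def test_roots_need_8_entries(self):
        with pytest.raises(ValueError, match="8"):
            _state(roots=(5, 5))


class TestGeneration:
    def test_degenerate_config_no_defects_constant_roots(self):
        cfg = GeneratorConfig(
            category_prevalence=(0,) * 7,
            defect_count_distribution=("constant", {"value": 0}),
            root_distribution=("constant", {"value": 5}),
        )
        states = generate_seedling_state(cfg, 5)
        for s in states:
            assert s.defects == ()
            assert s.roots_per_view == (5,) * 8
            assert s.true_grade == "A"

    def test_same_seed_identical_states(self):
        cfg = GeneratorConfig(seed=123)
        assert generate_seedling_state(cfg, 20) == generate_seedling_state(cfg, 20)

    def test_different_seed_differs(self):
        a = generate_seedling_state(GeneratorConfig(seed=1), 20)
        b = generate_seedling_state(GeneratorConfig(seed=2), 20)
        assert a != b

    def test_defect_count_distribution_mean(self):
        """Monte-Carlo check: Poisson(3) defects per seedling."""
        cfg = GeneratorConfig(
            defect_count_distribution=("poisson", {"lam": 3.0}), seed=5
        )
        states = generate_seedling_state(cfg, 1000)
        mean = np.mean([len(s.defects) for s in states])
        assert mean == pytest.approx(3.0, abs=0.3)

    def test_invalid_distribution_names_field(self):
        with pytest.raises(ValueError, match="root_distribution"):
            GeneratorConfig(root_distribution=("gamma", {"k": 2}))

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError, match="n"):
            generate_seedling_state(GeneratorConfig(), 0)

    def test_true_grade_consistent_with_rules(self):
        states = generate_seedling_state(GeneratorConfig(seed=9), 100)
        for s in states:
            assert s.true_grade == derive_true_grade(s)


class TestDeriveTrueGrade:
    def test_flawless_seedling_is_grade_a(self):
        assert derive_true_grade(_state()) == "A"

    def test_huge_lesion_is_grade_c(self):
        big = _defect(size=0.05, views=SIDE_VIEW_ANGLES)  # S = 0.4 >= T_C
        assert derive_true_grade(_state(defects=[big])) == "C"

    def test_boundary_score_is_grade_b(self):
        """S exactly at the A/B threshold falls in the B band."""
        d = _defect(size=DEFAULT_THRESHOLDS.T_A, views=(0,))
        assert derive_true_grade(_state(defects=[d])) == "B"

    def test_poor_roots_drag_grade_down(self):
        assert derive_true_grade(_state(roots=(0,) * 8)) == "C"


class TestEmitDetections:
    def test_zero_noise_oracle_contract(self):
        d = _defect(views=(0, 45))
        state = _state(defects=[d])
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        assert len(emit_detections(state, 0, cfg, rng)) == 1
        assert len(emit_detections(state, 45, cfg, rng)) == 1
        assert len(emit_detections(state, 90, cfg, rng)) == 0

    def test_miss_rate_one_empty(self):
        d = _defect(views=(0,))
        cfg = GeneratorConfig(detector_miss_rate=1.0)
        out = emit_detections(_state(defects=[d]), 0, cfg, np.random.default_rng(0))
        assert len(out) == 0

    def test_miss_rate_binomial(self):
        """1000 instances at miss rate 0.2 retain 0.8 +/- 0.04."""
        cfg = GeneratorConfig(detector_miss_rate=0.2)
        rng = np.random.default_rng(11)
        state = _state(defects=[_defect(views=(0,), cx=0.5) for _ in range(1000)])
        out = emit_detections(state, 0, cfg, rng)
        assert len(out) / 1000 == pytest.approx(0.8, abs=0.04)

    def test_false_positives_added(self):
        cfg = GeneratorConfig(detector_false_positive_rate=2.0)
        rng = np.random.default_rng(3)
        counts = [len(emit_detections(_state(), 0, cfg, rng)) for _ in range(200)]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.3)

    def test_root_mode_counts_roots(self):
        state = _state(roots=(0, 1, 2, 3, 4, 5, 6, 7))
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        for i, v in enumerate(SIDE_VIEW_ANGLES):
            out = emit_detections(state, v, cfg, rng, kind="side-root")
            assert len(out) == state.roots_per_view[i]

    def test_top_mode_emits_flags(self):
        state = _state(damage=True, shrink=True)
        out = emit_detections(state, "top", GeneratorConfig(),
                              np.random.default_rng(0), kind="top")
        assert {d.category for d in out} == {"Leaf damage", "Leaf shrinkage"}


class TestRendering:
    def test_top_view_dimensions(self):
        rgb, depth = render_top_view(_state())
        assert rgb.shape == (480, 640, 3)
        assert depth.shape == (480, 640)

    def test_shrinkage_shortens_upper_leaves(self):
        def upper_extent(state):
            _, depth = render_top_view(state)
            rows = np.where((depth == 200).any(axis=1))[0]
            return rows.max() - rows.min()

        def lower_extent(state):
            _, depth = render_top_view(state)
            cols = np.where((depth == 100).any(axis=0))[0]
            return cols.max() - cols.min()

        shrunk = _state(shrink=True)
        normal = _state()
        assert upper_extent(shrunk) < lower_extent(shrunk)
        assert upper_extent(normal) >= lower_extent(normal)

    def test_no_defects_no_lesion_pixels(self):
        rgb, depth = render_top_view(_state())
        lesion = (rgb == (123, 74, 34)).all(axis=2)
        assert lesion.sum() == 0

    def test_upper_leaf_lesion_rendered(self):
        d = _defect(size=0.01, views=(0,), upper=True)
        rgb, _ = render_top_view(_state(defects=[d]))
        lesion = (rgb == (123, 74, 34)).all(axis=2)
        assert lesion.sum() > 0

    def test_side_view_root_strokes_scale_with_count(self):
        many = render_side_view(_state(roots=(8,) * 8), 0)
        none = render_side_view(_state(roots=(0,) * 8), 0)
        root_color = (206, 212, 180)
        assert (many == root_color).all(axis=2).sum() > 0
        assert (none == root_color).all(axis=2).sum() == 0


class TestDatasetExport:
    def test_write_dataset_layout_and_determinism(self, tmp_path):
        cfg = GeneratorConfig(seed=3)
        states = generate_seedling_state(cfg, 2)
        m1 = write_dataset(tmp_path / "a", states, cfg, render=False)
        m2 = write_dataset(tmp_path / "b", states, cfg, render=False)
        assert m1["n"] == 2
        assert (tmp_path / "a" / "manifest.json").read_text() == (
            tmp_path / "b" / "manifest.json"
        ).read_text()
        labels = sorted(p.name for p in (tmp_path / "a" / "labels").iterdir())
        # per seedling: 1 top + 8 leaf + 8 root annotation files
        assert len(labels) == 2 * 17
        truth = json.loads(
            (tmp_path / "a" / "truth" / "seedling-0000.json").read_text()
        )
        assert truth["true_grade"] == states[0].true_grade
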