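# Methods

## The grading problem

A 2.5-inch Phalaenopsis potted seedling is imaged once from above (RGB +
registered depth, 640×480) and eight times from the side at 45° turntable
increments. The grading system must turn per-image object detections —
leaf-surface defects in seven categories, individual visible roots, and
top-view damage/shrinkage flags — into one of three commercial quality
grades. Two routes are implemented: an interpretable three-stage pipeline
whose intermediate quantities (counts, areas, score, root grade) justify
every decision, and a fast direct method that majority-votes per-image
grades.

## Score model and grade combination

The severity core is the weighted defect score `S = Σᵢ wᵢ·Aᵢ` over the
seven categories, where `Aᵢ` is the total detected box area of category
*i* accumulated across the configured side views and `wᵢ > 0` an expert
severity weight (default 1 for every category; farms supply their own).
Areas are kept in normalized image-area units by default (box `w·h`), with
pixel² available when image dimensions are attached; box area stands in for
lesion area because detectors emit boxes, not segmentations.

Score bands are half-open: `S < T_A → A`, `T_A ≤ S < T_C → B`,
`S ≥ T_C → C`. The root grade maps `G=3→A, 2→B, 1→C`. Because the two
channels can disagree (a clean-leaf seedling with dead roots), a
combination policy resolves them. The default is **worse-of** (severity
maximum): calling a poor seedling healthy is the costliest error in
commercial inspection, so neither channel may upgrade the other.
`score_priority` and `root_priority` are available for sensitivity checks.
Majority-vote ties in the direct method break toward the worse grade for
the same reason.

Default thresholds are `T_A = 0.005`, `T_C = 0.03` in normalized-area
units: with the synthetic population below, these put roughly a fifth of
seedlings in each of the A and C grades and the bulk in B, matching the
grade composition of a typical incoming-inspection batch. `calibrate_thresholds`
recovers cut points from labeled data by grid search over score quantiles
(25 quantiles, 5-fold stratified CV, maximizing the support-weighted F1 of
the rule-based grader; ties break toward the larger A band, and grid pairs
with `T_A ≥ T_C` are skipped).

## Root rule table

Each side view's root count is binned (≥3 / exactly 2 / ≤1) and the eight
views summarized as (a, b, c) with a+b+c=8. An ordered rule list — nine
shipped rows, best grade evaluated first — maps summaries to G ∈ {1,2,3}.
The shipped rows do not cover all 45 summaries; uncovered combinations fall
to a documented fallback (c ≥ 2 → grade 1; else a ≥ 5 → grade 2; else
grade 1), chosen to extend the table's own pattern: two or more weak views
always mean the bottom grade, and middling-heavy summaries sit in the
middle. Every decision reports whether the fallback fired, and
`enumerate_rule_table` exports the full 45-row audit. Rules are data
(YAML-loadable), not code.

## Stage models

* **Count regression** (`DefectCountSVR`): seven independent ε-SVR units
  (RBF kernel, C=10, ε=0.1 defaults; all configurable) over the 56-d
  view-major count matrix. Each unit reads its own category's eight view
  columns — the only features informative for its target — and learns to
  divide out the cross-view duplication factor of lesions visible from a
  contiguous arc of angles. Predictions are clipped at zero; half-up
  rounded copies are provided for reporting; constant training targets are
  flagged, not fatal.
* **Root grading** (`RootGradeForest`): 100 trees, unlimited depth, seed
  42. Alongside the raw 8 counts, every tree sees the three view-bin
  tallies (a, b, c): axis-aligned splits cannot count across features, and
  the tallies are exactly the summary the grading standard is written in.
  With them, the forest recovers the rule table essentially perfectly from
  labeled examples; without them it plateaus near 92%. Single-class
  training data is rejected with a pointer to the deterministic rule
  grader.
* **Quality classification** (`QualityGradeSVC`): linear-kernel SVM,
  C=10, class weights inverse to class frequency, features standardized on
  the training split only. The trailing root-grade feature is one-hot
  encoded internally: grade C is the union "poor roots OR large score",
  which no single ordinal coefficient can express under a linear kernel;
  with indicator columns the band/root decision structure becomes linearly
  representable. The classifier is trained on the *predicted* outputs of
  the fitted stage-2 models so train- and inference-time inputs share a
  distribution.

Training is deterministic under fixed seeds; fitted bundles persist to a
versioned directory (joblib + JSON metadata) and round-trip with
bit-identical predictions.

## Synthetic data generator

The generator emulates an incoming-inspection batch, not photographs:

* defects per seedling ~ Poisson(1.5), giving ≈22% defect-free seedlings —
  the defect-free fraction of a realistic commercial batch;
* category uniform over the seven labels (real prevalences are
  farm-specific);
* lesion area lognormal(μ=−5.5, σ=0.8) in normalized units (median ≈0.4%
  of the image), clipped to [5×10⁻⁴, 0.05];
* each lesion visible from a contiguous arc of 1–4 views
  (P = .35/.30/.20/.15), so the same instance is re-detected from adjacent
  angles — the duplication the count model must undo;
* per-view root counts ~ Poisson(5), yielding vigorous-but-variable roots
  (~60% of seedlings reach root grade 3, ~4% fall to grade 1);
* top-view flags derived from upper-leaf damage/shrinkage instances;
* detector noise: independent per-detection misses (rate 0 by default) and
  Poisson spurious boxes.

The ground-truth grade is *defined* as the rule-based combiner applied to
the state's true integrated areas and rule-derived root grade, so a
zero-noise oracle detector followed by the rule-substitute pipeline
reproduces the truth exactly — the round-trip invariant the test suite
asserts at 100%. Rendering is schematic (leaf ellipses, lesion blobs, root
strokes on white; depth encodes leaf layering with upper leaves nearer):
adequate for masking/brightness harnesses, deliberately not photorealistic.
Consequently, passing tests demonstrate the correctness of aggregation,
scoring, learning and evaluation logic under known truth; they say nothing
about real detector accuracy on real orchids, which requires real imagery
and trained detectors.

## Preprocessing

Top view: depth registered to RGB by a per-rig integer pixel offset
(default (0,0); exposed borders fill 0); plant mask from grayscale →
Gaussian blur (σ=1) → Otsu threshold (plant darker than the white
background) → largest connected component → hole filling → morphological
closing (disk radius 3); depth cleaned by zeroing outside the mask,
clipping in-mask values to the [1, 99] percentile band and min–max
rescaling to 0–255 (a constant in-mask depth maps to 0 by convention);
fusion stacks R,G,B,D. Side view: fixed crop of 600/650/300/0 pixels
(left/right/top/bottom), matching the constant capture geometry; no
resampling. Detector input: bilinear resize to 640×640, channels
preserved. Brightness: `B = clip(round(α·I), 0, 255)` — the clipping is not
part of the linear model but keeps images 8-bit valid. Coordinates are
0-based, (x=column, y=row), half-open crop intervals.

## Evaluation

Per-class precision/recall/F1 with support-weighted overall means
(weights nᵢ/Σnᵢ); zero denominators return 0 with an explicit flag.
Regression: MAE, RMSE, R² (R² is NaN-flagged for constant targets with
nonzero residual). The ablation harness runs the pipeline under named
view-combination presets (a packaged registry of 27: the full set, eight
single-angle drops, and the 6-, 5- and 4-view combinations; removed views
contribute zero-padded features unless the caller retrains). The
brightness harness re-runs detection and grading per α and reports one row
per coefficient; at α=1 it is bit-identical to the baseline.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use populations of 200–1000
synthetic seedlings with 800/200 train/test splits — large enough for
stable Monte-Carlo checks (binomial tolerances ±0.04 at n=1000) while the
whole suite runs in well under a minute. Determinism: every stochastic
component takes a seed; one global seed fans out to per-module seeds via
SHA-256. Grade-vote ties and calibration-grid ties have documented,
deterministic tie-breaks (worse grade; larger A band).

## Known limitations

* Detector behavior is idealized; miss/false-positive noise is independent
  per detection, not correlated across adjacent views as real occlusion
  would be.
* Box area is a proxy for lesion area; heavily elongated lesions are
  over-counted relative to segmentation-based area.
* The rule-table fallback for uncovered (a,b,c) summaries is a package
  convention; farms with an authoritative standard should supply a full
  rule file.
* The direct method's per-image voter is a rule-based stand-in (per-view
  score bands + root bins); a deployed system would put a trained per-image
  classifier behind the same vote combiner.
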