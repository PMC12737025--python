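"""Detection data types, YOLO-style annotation I/O, and the detector contract.

Stage 1 of the grading pipeline is object detection: leaf-surface defects in
the top view and the eight side views, and individual visible roots in the
side views.  Real detectors (YOLO-family networks) live outside this package;
here we define the in-memory representation of their outputs, the plain-text
annotation format used to exchange them, and a small detector interface with
two shipped implementations — a ground-truth oracle backed by a synthetic
seedling state, and an adapter that replays annotation files from disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, Union

import numpy as np

__all__ = [
    "SIDE_VIEW_ANGLES",
    "CategoryScheme",
    "SIDE_SCHEME",
    "ROOT_SCHEME",
    "TOP_SCHEME",
    "Detection",
    "DetectionSet",
    "read_yolo_annotations",
    "write_yolo_annotations",
    "count_by_category",
    "DetectorInterface",
    "YoloTxtDetector",
    "detect",
]

#: The eight side-view turntable positions, clockwise from the orientation of
#: greatest upper-leaf spread.
SIDE_VIEW_ANGLES: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)

View = Union[int, str]  # 0,45,...,315 or "top"


def _check_view(view: View) -> View:
    if view == "top" or view in SIDE_VIEW_ANGLES:
        return view
    raise ValueError(
        f"invalid view {view!r}: expected 'top' or one of {SIDE_VIEW_ANGLES}"
    )


@dataclass(frozen=True)
class CategoryScheme:
    """An ordered label set; class indices in annotation files follow it."""

    name: str
    labels: tuple[str, ...]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in scheme {self.name!r}") from None

    def label(self, index: int) -> str:
        if not 0 <= index < len(self.labels):
            raise KeyError(
                f"class index {index} out of range for scheme {self.name!r} "
                f"({len(self.labels)} labels)"
            )
        return self.labels[index]


#: The seven defect categories counted by the pipeline.  "Flawless" is a
#: detector-side class only and is excluded from all count/area features.
DEFECT_CATEGORIES: tuple[str, ...] = (
    "Disease",
    "Pest damage",
    "Pesticide damage",
    "Leaf damage",
    "Leaf shrinkage",
    "Variation",
    "Lower-leaf yellowing",
)

SIDE_SCHEME = CategoryScheme("side-leaf", DEFECT_CATEGORIES + ("Flawless",))
#: One detection per visible root; counting/binning happens downstream.
ROOT_SCHEME = CategoryScheme("side-root", ("Root",))
TOP_SCHEME = CategoryScheme("top-leaf", ("Leaf damage", "Leaf shrinkage"))


@dataclass(frozen=True)
class Detection:
    """One detected box with normalized center/size coordinates in [0, 1]."""

    category: str
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cx - self.w / 2 < -1e-9 or self.cx + self.w / 2 > 1 + 1e-9:
            raise ValueError(f"box exceeds horizontal bounds: cx={self.cx}, w={self.w}")
        if self.cy - self.h / 2 < -1e-9 or self.cy + self.h / 2 > 1 + 1e-9:
            raise ValueError(f"box exceeds vertical bounds: cy={self.cy}, h={self.h}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area_norm(self) -> float:
        """Box area as a fraction of the image area."""
        return self.w * self.h

    def area_px(self, image_dims: tuple[int, int]) -> float:
        """Box area in pixels, given (width, height) of the image."""
        width, height = image_dims
        return self.w * self.h * width * height


@dataclass
class DetectionSet:
    """All detections produced for one image under one category scheme."""

    image_id: str
    view: View
    scheme: CategoryScheme
    detections: list[Detection] = field(default_factory=list)
    image_dims: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self) -> None:
        _check_view(self.view)
        for det in self.detections:
            self.scheme.index(det.category)  # raises on scheme mismatch

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def sorted(self) -> "DetectionSet":
        dets = sorted(
            self.detections,
            key=lambda d: (self.scheme.index(d.category), d.cx, d.cy),
        )
        return DetectionSet(self.image_id, self.view, self.scheme, dets, self.image_dims)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_id": self.image_id,
                "view": self.view,
                "scheme": self.scheme.name,
                "image_dims": self.image_dims,
                "detections": [
                    {
                        "category": d.category,
                        "cx": d.cx,
                        "cy": d.cy,
                        "w": d.w,
                        "h": d.h,
                        "confidence": d.confidence,
                    }
                    for d in self.detections
                ],
            },
            indent=2,
        )


def read_yolo_annotations(
    path: str | Path,
    scheme: CategoryScheme,
    image_dims: tuple[int, int] | None = None,
    *,
    image_id: str | None = None,
    view: View = "top",
) -> DetectionSet:
    """Read one annotation file: ``class cx cy w h [conf]`` per line, normalized.

    Malformed lines are rejected with their 1-based line number; unknown class
    indices raise naming the scheme.
    """
    path = Path(path)
    detections: list[Detection] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(
                f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
            )
        try:
            idx = int(parts[0])
            nums = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        try:
            label = scheme.label(idx)
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: {exc.args[0]}") from None
        conf = nums[4] if len(nums) == 5 else None
        try:
            detections.append(Detection(label, *nums[:4], confidence=conf))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return DetectionSet(
        image_id=image_id or path.stem,
        view=view,
        scheme=scheme,
        detections=detections,
        image_dims=image_dims,
    )


def write_yolo_annotations(dset: DetectionSet, path: str | Path) -> None:
    """Write one line per detection, 6 decimal places, deterministic order.

    Lines are sorted by (class index, cx, cy).  Detections without a
    confidence produce 5-column lines; with one, 6 columns.
    """
    lines = []
    for det in dset.sorted():
        cols = [
            str(dset.scheme.index(det.category)),
            f"{det.cx:.6f}",
            f"{det.cy:.6f}",
            f"{det.w:.6f}",
            f"{det.h:.6f}",
        ]
        if det.confidence is not None:
            cols.append(f"{det.confidence:.6f}")
        lines.append(" ".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def count_by_category(
    dset: DetectionSet, scheme: CategoryScheme | None = None
) -> np.ndarray:
    """Per-label detection counts in scheme order.

    For the side-leaf scheme the returned vector has 7 entries: the
    "Flawless" class never enters count features.
    """
    scheme = scheme or dset.scheme
    if scheme is not dset.scheme and scheme.labels != dset.scheme.labels:
        raise ValueError(
            f"scheme mismatch: set uses {dset.scheme.name!r}, asked for {scheme.name!r}"
        )
    labels = [lab for lab in scheme.labels if lab != "Flawless"]
    counts = np.zeros(len(labels), dtype=int)
    for det in dset:
        if det.category == "Flawless":
            continue
        counts[labels.index(det.category)] += 1
    return counts


class DetectorInterface(Protocol):
    """Contract for stage-1 detectors: image in, DetectionSet out."""

    scheme: CategoryScheme

    def detect(self, image: np.ndarray, *, image_id: str, view: View) -> DetectionSet:
        ...


class YoloTxtDetector:
    """Adapter replaying externally produced annotation files.

    Maps ``(image_id, view)`` to a file ``<image_id>_<view>.txt`` under a root
    directory, so real detector outputs can drive the pipeline unchanged.
    """

    def __init__(self, root: str | Path, scheme: CategoryScheme,
                 image_dims: tuple[int, int] | None = None):
        self.root = Path(root)
        self.scheme = scheme
        self.image_dims = image_dims

    def detect(self, image: np.ndarray, *, image_id: str, view: View) -> DetectionSet:
        path = self.root / f"{image_id}_{view}.txt"
        return read_yolo_annotations(
            path, self.scheme, self.image_dims, image_id=image_id, view=view
        )


def detect(image: np.ndarray, model: DetectorInterface, *,
           image_id: str = "image", view: View = "top",
           expected_scheme: CategoryScheme | None = None) -> DetectionSet:
    """Run a detector on one image, checking the scheme against the stage."""
    if expected_scheme is not None and model.scheme.labels != expected_scheme.labels:
        raise ValueError(
            f"detector scheme {model.scheme.name!r} does not match pipeline "
            f"stage scheme {expected_scheme.name!r}"
        )
    return model.detect(image, image_id=image_id, view=view)


def concat_sets(sets: Iterable[DetectionSet]) -> list[Detection]:
    """Flatten several sets into one detection list (order preserved)."""
    out: list[Detection] = []
    for s in sets:
        out.extend(s.detections)
    return out
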