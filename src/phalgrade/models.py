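"""Trainable stage-2/3 learners as scikit-learn style estimators.

Three estimators mirror the learned stages of the grading pipeline:

* :class:`DefectCountSVR` — seven independent support-vector regressors
  (one per defect category) mapping the 56-d per-view count features to the
  seedling's true per-category defect totals, undoing the multi-view
  duplication of the same lesion;
* :class:`RootGradeForest` — a random forest over the 8-d per-view root
  count vector, voting a root grade in {1, 2, 3};
* :class:`QualityGradeSVC` — a standardized linear-kernel, class-balanced
  SVM over the 17-d seedling feature vector, emitting A/B/C.

All three follow the sklearn estimator contract (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with pipelines and model selection.  Training is deterministic
under a fixed ``random_state``; fitted bundles round-trip through
:func:`save_bundle` / :func:`load_bundle` with bit-identical predictions.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "DefectCountSVR",
    "RootGradeForest",
    "QualityGradeSVC",
    "evaluate_regression",
    "save_bundle",
    "load_bundle",
]

_BUNDLE_FORMAT = 1


class DefectCountSVR(BaseEstimator, RegressorMixin):
    """Per-category defect-count regression from 56-d multi-view counts.

    Each of the seven regressors is dedicated to one defect category: it is
    trained on that category's eight per-view count columns (view-major
    layout, columns ``i, i+7, ..., i+49``), which is where all the signal
    for its target lives.  The cross-view duplication factor — one lesion
    re-detected from a contiguous arc of adjacent angles — is what the
    regression learns to divide out.

    Parameters
    ----------
    kernel, C, epsilon, gamma : SVR hyperparameters shared by the seven
        per-category regressors (RBF kernel, C=10, epsilon=0.1 by default).
    clip_negative : report predictions clipped at zero (counts cannot be
        negative); raw values stay available via ``predict(raw=True)``.
    """

    def __init__(self, kernel: str = "rbf", C: float = 10.0,
                 epsilon: float = 0.1, gamma: str | float = "scale",
                 clip_negative: bool = True):
        self.kernel = kernel
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma
        self.clip_negative = clip_negative

    @staticmethod
    def _category_columns(X: np.ndarray, i: int) -> np.ndarray:
        return X[:, i::7]

    def fit(self, X, Y):
        X, Y = check_X_y(X, Y, multi_output=True)
        if X.shape[1] != 56:
            raise ValueError(
                f"X must have 56 features (8 views x 7 categories), got "
                f"{X.shape[1]}"
            )
        if Y.ndim != 2 or Y.shape[1] != 7:
            raise ValueError(f"Y must be (n, 7) per-category counts, got {Y.shape}")
        if X.shape[0] < 10:
            raise ValueError(f"need at least 10 training samples, got {X.shape[0]}")
        self.n_features_in_ = X.shape[1]
        self.estimators_ = []
        self.constant_targets_ = []
        for i in range(7):
            y = Y[:, i]
            if np.ptp(y) == 0:
                self.constant_targets_.append(i)
            est = make_pipeline(
                StandardScaler(),
                SVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon,
                    gamma=self.gamma),
            )
            est.fit(self._category_columns(X, i), y)
            self.estimators_.append(est)
        return self

    def predict(self, X, raw: bool = False):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        pred = np.column_stack(
            [est.predict(self._category_columns(X, i))
             for i, est in enumerate(self.estimators_)]
        )
        if self.clip_negative and not raw:
            pred = np.clip(pred, 0.0, None)
        return pred

    def predict_rounded(self, X):
        """Half-up rounded, zero-clipped counts for reporting."""
        return np.floor(self.predict(X) + 0.5).clip(0).astype(int)

    def training_report(self) -> dict:
        check_is_fitted(self, "estimators_")
        return {
            "n_regressors": 7,
            "constant_targets": list(self.constant_targets_),
            "hyperparams": {"kernel": self.kernel, "C": self.C,
                            "epsilon": self.epsilon, "gamma": self.gamma},
        }


class RootGradeForest(BaseEstimator, ClassifierMixin):
    """Random-forest root grading over 8-d per-view root counts.

    Each tree votes a grade in {1, 2, 3}; the forest reports the majority.
    Alongside the raw counts, every tree sees the three view-bin tallies —
    how many views show >=3, exactly 2, and <=1 visible roots — the standard
    summary nursery graders work from.  Axis-aligned splits cannot count
    across features, so providing the tallies lets shallow trees express
    exactly the cross-view patterns root standards are written in.

    Refuses single-class training data (use the deterministic rule table
    instead in that case).
    """

    def __init__(self, n_estimators: int = 100, max_depth: int | None = None,
                 random_state: int = 42, add_bin_tallies: bool = True):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state
        self.add_bin_tallies = add_bin_tallies

    def _augment(self, X: np.ndarray) -> np.ndarray:
        if not self.add_bin_tallies:
            return X
        a = (X >= 3).sum(axis=1, keepdims=True)
        b = (X == 2).sum(axis=1, keepdims=True)
        c = (X <= 1).sum(axis=1, keepdims=True)
        return np.hstack([X, a, b, c])

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 8:
            raise ValueError(f"X must have 8 per-view counts, got {X.shape[1]}")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "single-class training data: a forest cannot be fit; use "
                "root_rules.rule_grade as the deterministic substitute"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
        ).fit(self._augment(X), y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._augment(check_array(X)))

    def tree_votes(self, X):
        """Per-tree grade votes, shape (n_samples, n_trees)."""
        check_is_fitted(self, "forest_")
        X = self._augment(check_array(X))
        # trees emit encoded class indices; map back to grade labels
        return np.column_stack(
            [self.forest_.classes_[t.predict(X).astype(int)]
             for t in self.forest_.estimators_]
        )


class QualityGradeSVC(BaseEstimator, ClassifierMixin):
    """Linear-kernel maximum-margin A/B/C classifier over the 17-d seedling
    feature vector; features standardized on the training data only, class
    weights inverse to class frequency to absorb grade imbalance.

    The trailing root-grade feature is categorical (1/2/3), and the grade
    semantics are not linear in it — the lowest quality grade is "poor roots
    OR large defect score", a union a single ordinal coefficient cannot
    express.  The classifier therefore one-hot encodes the root grade
    internally, which makes the score-band / root-grade decision structure
    linearly representable.  Inputs remain the plain 17-d vectors.
    """

    def __init__(self, C: float = 10.0, class_weight: str | dict = "balanced",
                 one_hot_root: bool = True, random_state: int = 42):
        self.C = C
        self.class_weight = class_weight
        self.one_hot_root = one_hot_root
        self.random_state = random_state

    def _encode(self, X: np.ndarray) -> np.ndarray:
        if not self.one_hot_root:
            return X
        g = X[:, -1]
        return np.column_stack([X[:, :-1], g == 1, g == 2, g == 3]).astype(float)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 3:
            raise ValueError(
                f"all three grades must be present in training data, got {classes}"
            )
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SVC(kernel="linear", C=self.C, class_weight=self.class_weight,
                random_state=self.random_state),
        ).fit(self._encode(X), y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(self._encode(check_array(X)))

    @property
    def scaler_(self) -> StandardScaler:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.named_steps["standardscaler"]


def evaluate_regression(y, y_hat) -> tuple[float, float, float]:
    """(MAE, RMSE, R^2) for a prediction/target pair.

    MAE = mean |y - y_hat|; RMSE = sqrt(mean (y - y_hat)^2);
    R^2 = 1 - SS_res / SS_tot.  With a constant target, R^2 is undefined:
    returns NaN (flagged missing) unless the fit is exact, in which case 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 1:
        raise ValueError("need at least one sample")
    resid = y - y_hat
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return mae, rmse, r2


def save_bundle(path: str | Path, *, count_model=None, root_model=None,
                quality_model=None, metadata: dict | None = None) -> None:
    """Persist fitted stage models to a versioned on-disk bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"format_version": _BUNDLE_FORMAT, "models": {}}
    meta.update(metadata or {})
    for name, model in (("count", count_model), ("root", root_model),
                        ("quality", quality_model)):
        if model is not None:
            joblib.dump(model, path / f"{name}_model.joblib")
            meta["models"][name] = type(model).__name__
    (path / "bundle.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_bundle(path: str | Path) -> dict:
    """Load a model bundle; returns {'count': ..., 'root': ..., 'quality':
    ..., 'metadata': ...} with None for absent models."""
    path = Path(path)
    meta_path = path / "bundle.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a model bundle: {path} (no bundle.json)")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != _BUNDLE_FORMAT:
        raise ValueError(
            f"unsupported bundle format {meta.get('format_version')!r}"
        )
    out = {"metadata": meta}
    for name in ("count", "root", "quality"):
        f = path / f"{name}_model.joblib"
        out[name] = joblib.load(f) if f.exists() else None
    return out
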