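"""Training and evaluation of the six-gesture answer classifier.

The six answer gestures are single or double thumb taps with the index,
middle or ring finger, encoded 1-6 (1 index, 2 middle, 3 ring, 4 double
index, 5 double middle, 6 double ring). Two kernel-machine configurations
are provided: an RBF support vector machine (C=4, gamma=0.0078125) and an
SMO-style polynomial-kernel machine (C=11, degree 1). Evaluation is
stratified tenfold cross-validation with per-class precision computed from
the pooled confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import gesture_features as gf
from . import gesture_segmentation as gs
from . import inertial_signals as isg

__all__ = [
    "GestureLabel",
    "ClassifierConfig",
    "EvaluationReport",
    "GestureModel",
    "LABELS",
    "train",
    "predict",
    "cross_validate",
    "answer_query",
]

_FINGERS = ("index", "middle", "ring")
_TAPS = ("single", "double")


@dataclass(frozen=True, order=True)
class GestureLabel:
    """One of the six valid answer gestures."""

    finger: str
    taps: str

    def __post_init__(self) -> None:
        if self.finger not in _FINGERS:
            raise ValueError(f"finger must be one of {_FINGERS}")
        if self.taps not in _TAPS:
            raise ValueError(f"taps must be one of {_TAPS}")

    @property
    def code(self) -> int:
        """1 index, 2 middle, 3 ring, 4 double index, 5 double middle, 6 double ring."""
        return _FINGERS.index(self.finger) + 1 + (3 if self.taps == "double" else 0)

    @classmethod
    def from_code(cls, code: int) -> "GestureLabel":
        if not 1 <= code <= 6:
            raise ValueError("gesture code must be 1..6")
        return cls(finger=_FINGERS[(code - 1) % 3],
                   taps="double" if code > 3 else "single")

    def __str__(self) -> str:
        return f"{self.taps}-{self.finger}"


#: The six labels in code order.
LABELS = tuple(GestureLabel.from_code(c) for c in range(1, 7))


@dataclass(frozen=True)
class ClassifierConfig:
    """family 'svm_rbf' (C=4, gamma=0.0078125) or 'svm_poly' (C=11, degree 1)."""

    family: str = "svm_rbf"
    cost: Optional[float] = None
    gamma: float = 0.0078125
    degree: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("svm_rbf", "svm_poly"):
            raise ValueError("family must be svm_rbf or svm_poly")
        if self.cost is None:
            object.__setattr__(self, "cost", 4.0 if self.family == "svm_rbf" else 11.0)
        if self.cost <= 0:
            raise ValueError("cost must be positive")


@dataclass
class GestureModel:
    """A fitted classifier plus the bookkeeping needed to apply it safely."""

    svc: SVC
    config: ClassifierConfig
    n_features: int
    normalizer: Optional[gf.NormalizationModel] = None
    feature_version: str = gf.FEATURE_ORDER_VERSION


@dataclass
class EvaluationReport:
    """Pooled cross-validation outcome.

    confusion: rows = true class code, columns = predicted; per-class
    precision = TP / (TP + FP) on the pooled matrix; macro precision is the
    unweighted mean over classes.
    """

    confusion: pd.DataFrame
    per_class_precision: pd.Series
    macro_precision: float
    fold_assignment: np.ndarray

    def summary(self) -> str:
        lines = ["Confusion matrix (rows: true, cols: predicted)",
                 self.confusion.to_string(), "",
                 "Per-class precision:"]
        for name, p in self.per_class_precision.items():
            lines.append(f"  {name}: {p:.3f}")
        lines.append(f"Macro precision: {self.macro_precision:.3f}")
        return "\n".join(lines)


def _make_svc(cfg: ClassifierConfig) -> SVC:
    if cfg.family == "svm_rbf":
        return SVC(C=cfg.cost, kernel="rbf", gamma=cfg.gamma,
                   random_state=cfg.seed)
    return SVC(C=cfg.cost, kernel="poly", degree=cfg.degree, gamma=1.0,
               coef0=0.0, random_state=cfg.seed)


def _codes(labels: Sequence[Union[GestureLabel, int]]) -> np.ndarray:
    return np.array([l.code if isinstance(l, GestureLabel) else int(l)
                     for l in labels])


def train(features: np.ndarray, labels: Sequence[Union[GestureLabel, int]],
          cfg: Optional[ClassifierConfig] = None,
          normalizer: Optional[gf.NormalizationModel] = None) -> GestureModel:
    """Fit the kernel classifier on a normalized feature matrix."""
    cfg = cfg or ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = _codes(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train")
    svc = _make_svc(cfg)
    svc.fit(X, y)
    return GestureModel(svc=svc, config=cfg, n_features=X.shape[1],
                        normalizer=normalizer)


def predict(model: GestureModel, features: np.ndarray) -> List[GestureLabel]:
    """One label per row; rejection happens upstream in segmentation."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {X.shape[1]}")
    return [GestureLabel.from_code(int(c)) for c in model.svc.predict(X)]


def cross_validate(features: np.ndarray,
                   labels: Sequence[Union[GestureLabel, int]],
                   k: int = 10,
                   cfg: Optional[ClassifierConfig] = None,
                   seed: int = 0) -> EvaluationReport:
    """Stratified k-fold CV; precision from the pooled confusion matrix."""
    cfg = cfg or ClassifierConfig(seed=seed)
    X = np.asarray(features, dtype=float)
    y = _codes(labels)
    classes = np.unique(y)
    counts = np.bincount(y)[classes]
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(y.size, dtype=int)
    conf = np.zeros((classes.size, classes.size), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignment[te] = fold
        m = train(X[tr], y[tr], cfg)
        pred = m.svc.predict(X[te])
        for t, p in zip(y[te], pred):
            conf[idx[t], idx[p]] += 1
    names = [str(GestureLabel.from_code(int(c))) if 1 <= c <= 6 else str(c)
             for c in classes]
    confusion = pd.DataFrame(conf, index=names, columns=names)
    col_sums = conf.sum(axis=0)
    precisions = np.where(col_sums > 0, np.diag(conf) / np.maximum(col_sums, 1), 0.0)
    per_class = pd.Series(precisions, index=names)
    return EvaluationReport(confusion=confusion,
                            per_class_precision=per_class,
                            macro_precision=float(per_class.mean()),
                            fold_assignment=fold_assignment)


def answer_query(model: GestureModel, recording: isg.InertialRecording,
                 prompt_time_s: float, n_options: int,
                 seg_cfg: Optional[gs.SegmentationConfig] = None,
                 reference: Optional[isg.MagnitudeSeries] = None,
                 gravity_cutoff_hz: float = isg.DEFAULT_GRAVITY_CUTOFF_HZ):
    """Answer a multiple-choice prompt from a raw recording.

    Full pipeline: capture window after the prompt, DTW gesture gate,
    threshold segmentation, feature extraction, normalization, prediction.
    Returns ``(option, reason)`` where option is 1..n_options or the string
    ``"repeat"`` when the gate or the boundary rules reject (reason carries
    the rejection code), or when the predicted gesture exceeds n_options.
    """
    if not 2 <= n_options <= 6:
        raise ValueError("n_options must be in 2..6")
    seg_cfg = seg_cfg or gs.SegmentationConfig()
    if model.normalizer is None:
        raise ValueError("model has no stored normalizer")
    try:
        window = gs.capture_window(recording, prompt_time_s,
                                   seg_cfg.max_gesture_ms / 1000.0, seg_cfg)
    except ValueError:
        return "repeat", "truncated_window"
    window = isg.remove_gravity(window, gravity_cutoff_hz)
    gyro_mag = isg.magnitude(window, "gyroscope")
    if reference is not None and not gs.contains_gesture(gyro_mag, reference, seg_cfg):
        return "repeat", "no_gesture"
    seg = gs.segment_window(window, gyro_mag, seg_cfg)
    if isinstance(seg, gs.Rejection):
        return "repeat", seg.reason.value
    vec = gf.apply_normalizer(model.normalizer, gf.extract_features(seg))
    label = predict(model, vec.values[None, :])[0]
    if label.code > n_options:
        return "repeat", "out_of_range"
    return label.code, None
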