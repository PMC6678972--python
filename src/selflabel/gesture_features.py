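"""The 208-dimensional gesture feature vector and its [-1, 1] normalization.

From each 6-channel segment, 14 derived series are formed (per sensor:
X, Y, Z, the pairwise magnitudes XY, XZ, YZ, and the total magnitude XYZ).
Seven order statistics of each series give 98 time-domain features; the same
seven statistics of each series' one-sided FFT magnitude spectrum give 98
spectral features; two area-under-the-curve variants per raw component give
the remaining 12 — 208 in total. Features are min-max scaled to [-1, 1] on
training data so that no feature dominates the kernel by sheer magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .gesture_segmentation import GestureSegment

__all__ = [
    "FeatureVector",
    "NormalizationModel",
    "FEATURE_ORDER_VERSION",
    "derive_signals",
    "time_stats",
    "auc_features",
    "fft_stats",
    "extract_features",
    "feature_names",
    "fit_normalizer",
    "apply_normalizer",
]

#: Bump when the feature order or definitions change; persisted with models
#: to prevent silent train/predict mismatches.
FEATURE_ORDER_VERSION = "208-v1"

_SENSORS = ("acc", "gyr")
_SIGNALS = ("x", "y", "z", "xy", "xz", "yz", "xyz")
_STATS = ("mean", "max", "min", "sd", "q1", "q2", "q3")
_COMPONENTS = ("x", "y", "z")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)


def derive_signals(seg: GestureSegment) -> Dict[str, np.ndarray]:
    """The 14 per-sensor series: x, y, z, xy, xz, yz, xyz for each sensor."""
    rec = seg.recording
    out: Dict[str, np.ndarray] = {}
    for sensor, mat in (("acc", rec.acc()), ("gyr", rec.gyr())):
        x, y, z = mat.T
        out[f"{sensor}.x"] = x
        out[f"{sensor}.y"] = y
        out[f"{sensor}.z"] = z
        out[f"{sensor}.xy"] = np.sqrt(x * x + y * y)
        out[f"{sensor}.xz"] = np.sqrt(x * x + z * z)
        out[f"{sensor}.yz"] = np.sqrt(y * y + z * z)
        out[f"{sensor}.xyz"] = np.sqrt(x * x + y * y + z * z)
    return out


def time_stats(series: np.ndarray) -> np.ndarray:
    """[mean, max, min, sd, Q1, Q2, Q3].

    sd is the population standard deviation (ddof=0); quartiles use linear
    interpolation.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    q1, q2, q3 = np.percentile(s, [25, 50, 75])
    return np.array([s.mean(), s.max(), s.min(), s.std(ddof=0), q1, q2, q3])


def auc_features(seg: GestureSegment) -> np.ndarray:
    """Two area-under-the-curve features per raw component per sensor (12).

    Per component: the signed trapezoidal area (net excursion) and the
    trapezoidal area of the absolute value (total excursion).
    """
    rec = seg.recording
    dt = 1.0 / rec.sampling_rate_hz
    out: List[float] = []
    for mat in (rec.acc(), rec.gyr()):
        for comp in mat.T:
            out.append(float(np.trapezoid(comp, dx=dt)))
            out.append(float(np.trapezoid(np.abs(comp), dx=dt)))
    return np.asarray(out)


def fft_stats(series: np.ndarray) -> np.ndarray:
    """The seven time_stats measures on the one-sided FFT magnitude spectrum.

    Unnormalized forward transform; the spectrum includes the DC bin.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    spectrum = np.abs(np.fft.rfft(s))
    return time_stats(spectrum)


def feature_names() -> Tuple[str, ...]:
    """Canonical names in extraction order: 98 time, 12 AUC, 98 spectral."""
    names: List[str] = []
    for sensor in _SENSORS:
        for sig in _SIGNALS:
            names.extend(f"{sensor}.{sig}.{st}" for st in _STATS)
    for sensor in _SENSORS:
        for comp in _COMPONENTS:
            names.append(f"{sensor}.{comp}.auc")
            names.append(f"{sensor}.{comp}.absauc")
    for sensor in _SENSORS:
        for sig in _SIGNALS:
            names.extend(f"{sensor}.{sig}.fft.{st}" for st in _STATS)
    return tuple(names)


_NAMES = feature_names()


def extract_features(seg: GestureSegment) -> FeatureVector:
    """The full 208-element vector in the frozen canonical order."""
    sigs = derive_signals(seg)
    blocks = [time_stats(sigs[f"{sensor}.{sig}"])
              for sensor in _SENSORS for sig in _SIGNALS]
    blocks.append(auc_features(seg))
    blocks.extend(fft_stats(sigs[f"{sensor}.{sig}"])
                  for sensor in _SENSORS for sig in _SIGNALS)
    values = np.concatenate(blocks)
    assert values.size == 208
    return FeatureVector(values=values, names=_NAMES)


@dataclass(frozen=True)
class NormalizationModel:
    """Per-feature min/max fitted on training data, mapping to [-1, 1]."""

    mins: np.ndarray
    maxs: np.ndarray
    names: Tuple[str, ...]
    version: str = FEATURE_ORDER_VERSION

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "names": list(self.names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "NormalizationModel":
        d = json.loads(text)
        return cls(mins=np.asarray(d["mins"], dtype=float),
                   maxs=np.asarray(d["maxs"], dtype=float),
                   names=tuple(d["names"]), version=d["version"])


def fit_normalizer(vectors: Sequence[FeatureVector]) -> NormalizationModel:
    """Fit the per-feature min/max map from training vectors."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("need at least one training vector")
    names = vectors[0].names
    mat = np.vstack([v.values for v in vectors])
    return NormalizationModel(mins=mat.min(axis=0), maxs=mat.max(axis=0), names=names)


def apply_normalizer(model: NormalizationModel, vector: FeatureVector) -> FeatureVector:
    """Map to [-1, 1]: training min -> -1, max -> +1, linear in between.

    Constant training features map to 0; unseen values outside the training
    range are clipped to [-1, 1].
    """
    if vector.names != model.names:
        raise ValueError("feature order mismatch")
    span = model.maxs - model.mins
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0,
                          2.0 * (vector.values - model.mins) / np.where(span > 0, span, 1.0) - 1.0,
                          0.0)
    return FeatureVector(values=np.clip(scaled, -1.0, 1.0), names=vector.names)


def normalize_matrix(model: NormalizationModel,
                     vectors: Iterable[FeatureVector]) -> np.ndarray:
    """Stack normalized vectors into an (n, 208) matrix."""
    return np.vstack([apply_normalizer(model, v).values for v in vectors])
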