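"""Wrist IMU recordings: containers, CSV I/O, gravity removal, magnitudes.

The recordings carry six channels — three accelerometer axes in m/s² and
three gyroscope axes in rad/s — sampled at a fixed rate. On a smartwatch
worn on the non-dominant wrist, the X axis points along the arm toward the
fingers and the Z axis is perpendicular to the screen. Downstream gesture
detection works mostly on the *total angular velocity*, the Euclidean
magnitude of the three gyroscope axes, because it is insensitive to how the
wrist happens to be oriented when the gesture is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "InertialRecording",
    "MagnitudeSeries",
    "read_recording",
    "write_recording",
    "remove_gravity",
    "magnitude",
]

_COLUMNS = ("t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: Default sampling rate used by the synthetic fixtures, in Hz. Consumer
#: smartwatch IMUs commonly report in the 50-100 Hz range.
DEFAULT_SAMPLING_RATE_HZ = 50.0

#: Default cutoff of the gravity low-pass filter, in Hz. Gravity is a
#: quasi-DC component; hand gestures live well above 1 Hz.
DEFAULT_GRAVITY_CUTOFF_HZ = 0.3


@dataclass(frozen=True)
class InertialRecording:
    """A timestamped 6-channel IMU stream at a nominally fixed rate.

    Parameters
    ----------
    sampling_rate_hz : float
        Nominal sampling rate; must agree with the median timestamp
        increment to within 5%.
    t : ndarray
        Monotonically increasing sample times, seconds.
    acc_x, acc_y, acc_z : ndarray
        Acceleration, m/s².
    gyr_x, gyr_y, gyr_z : ndarray
        Angular velocity, rad/s.
    """

    sampling_rate_hz: float
    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyr_x: np.ndarray
    gyr_y: np.ndarray
    gyr_z: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.t, self.acc_x, self.acc_y, self.acc_z,
                  self.gyr_x, self.gyr_y, self.gyr_z]
        for name, arr in zip(_COLUMNS, arrays):
            object.__setattr__(self, name, np.asarray(arr, dtype=float))
        n = len(self.t)
        if n < 2:
            raise ValueError("empty recording: need at least 2 samples")
        if any(len(a) != n for a in arrays[1:]):
            raise ValueError("channel length mismatch")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("non-monotone time")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        med = float(np.median(dt))
        if abs(1.0 / med - self.sampling_rate_hz) > 0.05 * self.sampling_rate_hz:
            raise ValueError(
                f"sampling_rate_hz={self.sampling_rate_hz} inconsistent with "
                f"median timestamp spacing {med:.6f} s"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def acc(self) -> np.ndarray:
        """(n, 3) acceleration matrix."""
        return np.column_stack([self.acc_x, self.acc_y, self.acc_z])

    def gyr(self) -> np.ndarray:
        """(n, 3) angular-velocity matrix."""
        return np.column_stack([self.gyr_x, self.gyr_y, self.gyr_z])

    def slice_time(self, start_s: float, end_s: float) -> "InertialRecording":
        """Return the sub-recording with start_s <= t <= end_s."""
        mask = (self.t >= start_s - 1e-12) & (self.t <= end_s + 1e-12)
        if mask.sum() < 2:
            raise ValueError("slice too short")
        return InertialRecording(
            self.sampling_rate_hz,
            *(getattr(self, c)[mask] for c in _COLUMNS),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _COLUMNS})


@dataclass(frozen=True)
class MagnitudeSeries:
    """Non-negative per-sample magnitude (e.g. total angular velocity, rad/s)."""

    values: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def read_recording(path) -> InertialRecording:
    """Read a 6-channel IMU CSV (header t,acc_x,...,gyr_z, '.' decimals).

    Lines starting with '#' are treated as comments (unit annotations).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError("empty recording")
    if len(df) < 2:
        raise ValueError("empty recording: need at least 2 samples")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time")
    dt = float(np.median(np.diff(t)))
    return InertialRecording(1.0 / dt, *(df[c].to_numpy(dtype=float) for c in _COLUMNS))


def write_recording(rec: InertialRecording, path) -> None:
    """Write the CSV form read by :func:`read_recording`.

    Units (accelerometer m/s², gyroscope rad/s) are recorded as a comment.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# units: t s, acc_* m/s^2, gyr_* rad/s\n")
        rec.to_frame().to_csv(fh, index=False)


def remove_gravity(rec: InertialRecording,
                   cutoff_hz: float = DEFAULT_GRAVITY_CUTOFF_HZ) -> InertialRecording:
    """Subtract a low-pass gravity estimate from the acceleration channels.

    A first-order Butterworth low-pass at ``cutoff_hz`` is run forward and
    backward (zero phase lag) over each acceleration axis; the filtered
    track is the gravity estimate and is subtracted. Gyroscope channels are
    returned unchanged.
    """
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must be in (0, {nyq}); got {cutoff_hz}")
    b, a = _sig.butter(1, cutoff_hz / nyq, btype="low")
    out = {}
    for c in ("acc_x", "acc_y", "acc_z"):
        x = getattr(rec, c)
        gravity = _sig.filtfilt(b, a, x)
        out[c] = x - gravity
    return InertialRecording(
        rec.sampling_rate_hz, rec.t,
        out["acc_x"], out["acc_y"], out["acc_z"],
        rec.gyr_x, rec.gyr_y, rec.gyr_z,
    )


def magnitude(rec: InertialRecording, sensor: str) -> MagnitudeSeries:
    """Per-sample Euclidean magnitude of a sensor's three axes.

    ``sensor`` is ``"accelerometer"`` or ``"gyroscope"``; for the gyroscope
    this is the total angular velocity in rad/s.
    """
    if sensor == "accelerometer":
        m = rec.acc()
    elif sensor == "gyroscope":
        m = rec.gyr()
    else:
        raise ValueError(f"unknown sensor {sensor!r}")
    return MagnitudeSeries(np.linalg.norm(m, axis=1), rec.sampling_rate_hz)
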