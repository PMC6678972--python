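"""Prompt-window capture, DTW gesture gating and threshold segmentation.

A prompt (vibration/sound) opens a capture window; a stored gyroscope-
magnitude template and dynamic time warping decide whether the window
contains a gesture at all; the magnitude signal is then compressed into
~240 ms blocks and a two-threshold (hysteresis) rule locates the gesture's
start and end, with duration rules rejecting segments that are too short
(< 200 ms) or too long (> 1300 ms) and a guard that trims isolated terminal
spikes caused by sporadic movements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Union

import numpy as np

from .inertial_signals import InertialRecording, MagnitudeSeries

__all__ = [
    "SegmentationConfig",
    "GestureSegment",
    "Rejection",
    "RejectReason",
    "capture_window",
    "dtw_distance",
    "contains_gesture",
    "compress",
    "find_boundaries",
    "segment_window",
]


class RejectReason(str, Enum):
    NO_PEAK = "no_peak"
    TOO_SHORT = "too_short"
    TOO_LONG = "too_long"


@dataclass(frozen=True)
class Rejection:
    """Outcome of segmentation when no valid gesture is found (a value, not
    an error — the caller prompts the user to repeat)."""

    reason: RejectReason


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the gesture gate and boundary rules.

    window_ms
        Compression block length; the magnitude signal is averaged over
        non-overlapping blocks of this length.
    low_threshold / high_threshold
        Hysteresis pair on total angular velocity (rad/s). A block above the
        high threshold flags a candidate gesture; the low threshold locates
        where the signal rises from / falls back to rest. The levels were
        determined empirically; defaults are 0.15 / 0.4 rad/s.
    min_gesture_ms / max_gesture_ms
        Duration band for an acceptable gesture (200–1300 ms).
    peak_guard_ms / peak_guard_level
        A boundary closer than peak_guard_ms to an isolated block above
        peak_guard_level is assumed to sit on a sporadic spike, which is
        trimmed off.
    reaction_pad_s
        Extra capture time allowed for the user to react to the prompt.
    dtw_accept_threshold
        Largest per-reference-sample DTW distance for which a window is
        deemed to contain a gesture.
    """

    window_ms: float = 240.0
    low_threshold: float = 0.15
    high_threshold: float = 0.4
    min_gesture_ms: float = 200.0
    max_gesture_ms: float = 1300.0
    peak_guard_ms: float = 220.0
    peak_guard_level: float = 0.4
    reaction_pad_s: float = 1.5
    dtw_accept_threshold: float = 0.35

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be < high_threshold")
        if not self.min_gesture_ms < self.max_gesture_ms:
            raise ValueError("min_gesture_ms must be < max_gesture_ms")
        if self.dtw_accept_threshold < 0:
            raise ValueError("dtw_accept_threshold must be non-negative")


@dataclass(frozen=True)
class GestureSegment:
    """A boundary-trimmed 6-channel window, candidate for feature extraction."""

    recording: InertialRecording
    start_s: float
    end_s: float

    @property
    def duration_ms(self) -> float:
        return 1000.0 * (self.end_s - self.start_s)


def capture_window(rec: InertialRecording, prompt_time_s: float,
                   max_gesture_duration_s: float,
                   cfg: SegmentationConfig) -> InertialRecording:
    """Slice the recording from the prompt to the latest plausible gesture end.

    The window spans ``[prompt, prompt + max_gesture_duration + reaction_pad]``:
    the pad absorbs the user's reaction time after perceiving the prompt.
    """
    if not (rec.t[0] <= prompt_time_s <= rec.t[-1]):
        raise ValueError("prompt_time_s outside recording")
    end = prompt_time_s + max_gesture_duration_s + cfg.reaction_pad_s
    if end > rec.t[-1] + 0.5 / rec.sampling_rate_hz:
        raise ValueError("truncated window: recording ends before the capture window")
    return rec.slice_time(prompt_time_s, end)


def dtw_distance(a: Union[MagnitudeSeries, np.ndarray],
                 b: Union[MagnitudeSeries, np.ndarray]) -> float:
    """Classic dynamic-time-warping distance between two 1-D series.

    Absolute-difference local cost, full warping window, symmetric step
    pattern (match / insert / delete all cost one local step).
    """
    x = np.asarray(a.values if isinstance(a, MagnitudeSeries) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, MagnitudeSeries) else b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    n, m = x.size, y.size
    # Row-rolling DP over the |x_i - y_j| cost matrix.
    cost = np.abs(x[:, None] - y[None, :])
    prev = np.empty(m)
    prev[0] = cost[0, 0]
    for j in range(1, m):
        prev[j] = prev[j - 1] + cost[0, j]
    cur = np.empty(m)
    for i in range(1, n):
        cur[0] = prev[0] + cost[i, 0]
        ci = cost[i]
        for j in range(1, m):
            cur[j] = ci[j] + min(prev[j], cur[j - 1], prev[j - 1])
        prev, cur = cur, prev
    return float(prev[m - 1])


def contains_gesture(window: MagnitudeSeries, reference: MagnitudeSeries,
                     cfg: SegmentationConfig, hop: int = 5) -> bool:
    """DTW gate: does the window contain something shaped like the template?

    The reference template (gyroscope magnitude of one recorded gesture) is
    slid across the window; the gate passes if the minimum DTW distance,
    normalized by the reference length, is at or below
    ``cfg.dtw_accept_threshold``.
    """
    ref = np.asarray(reference.values, dtype=float)
    win = np.asarray(window.values, dtype=float)
    if ref.size == 0 or win.size == 0:
        raise ValueError("empty input")
    L = ref.size
    if win.size <= L:
        best = dtw_distance(win, ref)
    else:
        best = np.inf
        for start in range(0, win.size - L + 1, max(1, hop)):
            d = dtw_distance(win[start:start + L], ref)
            if d < best:
                best = d
    return best / L <= cfg.dtw_accept_threshold


def compress(window: MagnitudeSeries, cfg: SegmentationConfig) -> MagnitudeSeries:
    """Average the magnitude over non-overlapping ~240 ms blocks.

    A trailing partial block is averaged over the samples it actually has,
    so gestures near the window end remain detectable.
    """
    block = max(1, int(round(cfg.window_ms / 1000.0 * window.sampling_rate_hz)))
    v = np.asarray(window.values, dtype=float)
    if v.size < 1:
        raise ValueError("empty window")
    n_full = v.size // block
    means = []
    if n_full:
        means.append(v[: n_full * block].reshape(n_full, block).mean(axis=1))
    if v.size % block:
        means.append([v[n_full * block:].mean()])
    return MagnitudeSeries(np.concatenate([np.atleast_1d(m) for m in means]),
                           window.sampling_rate_hz / block)


def _trim_terminal_peaks(v: np.ndarray, start: int, end: int,
                         cfg: SegmentationConfig, block_ms: float):
    """Drop an isolated spike run touching either boundary (Fig.-3-style
    sporadic end peaks). A run of blocks above peak_guard_level that sits
    within peak_guard_ms of a boundary counts as an isolated spike when it
    is separated from the rest of the gesture by genuinely quiet blocks
    (below the low threshold); a double tap's second burst is bridged by
    above-low blocks and is never trimmed."""
    above = np.flatnonzero(v[start:end + 1] > cfg.peak_guard_level) + start
    if above.size == 0:
        return start, end
    # group consecutive indices into runs
    runs = np.split(above, np.flatnonzero(np.diff(above) > 1) + 1)
    guard_blocks = cfg.peak_guard_ms / block_ms

    def _quiet_between(a: int, b: int) -> bool:
        return a < b and bool(np.any(v[a:b + 1] < cfg.low_threshold))

    if len(runs) >= 2:
        last = runs[-1]
        if (end - last[-1]) < guard_blocks and \
                _quiet_between(runs[-2][-1] + 1, last[0] - 1):
            end = last[0] - 1
            while end > start and v[end] < cfg.low_threshold:
                end -= 1
        first = runs[0]
        if (first[0] - start) < guard_blocks and \
                _quiet_between(first[-1] + 1, runs[1][0] - 1):
            start = first[-1] + 1
            while start < end and v[start] < cfg.low_threshold:
                start += 1
    return start, end


def find_boundaries(compressed: MagnitudeSeries, cfg: SegmentationConfig,
                    raw: Optional[MagnitudeSeries] = None):
    """Locate gesture start/end from the compressed magnitude signal.

    Returns ``(start_s, end_s)`` in seconds relative to the window start, or
    a :class:`Rejection`. Blocks above the high threshold flag the gesture;
    the low threshold delimits it. When ``raw`` (the uncompressed magnitude
    the blocks were averaged from) is given, the boundaries are refined to
    the raw low-threshold crossings inside the boundary blocks, so the
    sub-block duration rules (200 ms minimum) are meaningful.
    """
    v = np.asarray(compressed.values, dtype=float)
    block_s = 1.0 / compressed.sampling_rate_hz
    block_ms = 1000.0 * block_s
    peaks = np.flatnonzero(v > cfg.high_threshold)
    if peaks.size == 0:
        return Rejection(RejectReason.NO_PEAK)
    # the gesture spans from the first to the last high crossing (a double
    # tap produces two high runs); the low threshold locates its edges
    start = int(peaks[0])
    while start > 0 and v[start - 1] >= cfg.low_threshold:
        start -= 1
    end = int(peaks[-1])
    while end < v.size - 1 and v[end + 1] >= cfg.low_threshold:
        end += 1

    def _duration_and_bounds(s_block: int, e_block: int):
        s_s = s_block * block_s
        e_s = (e_block + 1) * block_s
        if raw is not None:
            rv = np.asarray(raw.values, dtype=float)
            fs = raw.sampling_rate_hz
            blk = max(1, int(round(cfg.window_ms / 1000.0 * fs)))
            lo = s_block * blk
            hi = min(rv.size, (e_block + 1) * blk)
            active = np.flatnonzero(rv[lo:hi] >= cfg.low_threshold)
            if active.size:
                s_s = (lo + active[0]) / fs
                e_s = (lo + active[-1] + 1) / fs
        return s_s, e_s

    s_s, e_s = _duration_and_bounds(start, end)
    if 1000.0 * (e_s - s_s) < cfg.min_gesture_ms:
        return Rejection(RejectReason.TOO_SHORT)
    start, end = _trim_terminal_peaks(v, start, end, cfg, block_ms)
    s_s, e_s = _duration_and_bounds(start, end)
    if 1000.0 * (e_s - s_s) > cfg.max_gesture_ms:
        return Rejection(RejectReason.TOO_LONG)
    if 1000.0 * (e_s - s_s) < cfg.min_gesture_ms:
        return Rejection(RejectReason.TOO_SHORT)
    return s_s, e_s


def segment_window(window: InertialRecording, gyro_magnitude: MagnitudeSeries,
                   cfg: SegmentationConfig):
    """Compress, find boundaries, and trim the 6-channel window.

    Returns a :class:`GestureSegment` or a :class:`Rejection`.
    """
    comp = compress(gyro_magnitude, cfg)
    res = find_boundaries(comp, cfg, raw=gyro_magnitude)
    if isinstance(res, Rejection):
        return res
    s_s, e_s = res
    t0 = window.t[0]
    trimmed = window.slice_time(t0 + s_s, t0 + e_s)
    return GestureSegment(recording=trimmed, start_s=s_s, end_s=e_s)
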