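"""Deterministic synthetic generators emulating both study designs.

Gesture study: 15 participants x 6 gestures x 3 postures x 2 repetitions =
540 prompt-triggered wrist-IMU recordings. A tap is a Gaussian-windowed
oscillatory burst on the gyroscope axes whose per-axis amplitude mixture
encodes the finger (index/middle/ring); double taps are two bursts 120 ms
apart with a weaker, jittered second burst, so single vs double gestures of
the same finger overlap — deliberately imperfect class separation.
Participant and posture enter as random amplitude factors and small axis
rotations.

Audio study: 8 home-activity classes x 10 training clips (2.5-5.2 s at
16 kHz), synthesized as band-limited Gaussian noise with class-specific
spectral envelopes plus shallow amplitude modulation. The sink and shower
classes share one spectral envelope (sound-confusable) but have well
separated direction centroids (direction-separable); walking and
tooth-brushing are mobile sources. Fixed-source sample directions stay
within 0.18 of their class centroid. Five continuous sequences interleave
one instance of every trained class plus three unknown sounds (ringing
telephone, typing on a keyboard, teapot whistling) with silence gaps below
the gate's active level.

The generators are pure functions of (spec, seed); none of them aims for
acoustic realism, only for the statistical structure the pipelines consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .audio_frontend import AudioClip
from .gesture_classifier import GestureLabel
from .inertial_signals import (DEFAULT_SAMPLING_RATE_HZ, InertialRecording,
                               MagnitudeSeries)

__all__ = [
    "GestureFixtureSpec",
    "AudioFixtureSpec",
    "GestureSample",
    "AudioTrainingSet",
    "ContinuousSequence",
    "gen_gesture_dataset",
    "gen_audio_dataset",
    "gen_continuous_sequences",
    "canonical_tap_template",
    "AUDIO_CLASSES",
    "UNKNOWN_CLASSES",
]

GRAVITY = 9.81


# ---------------------------------------------------------------------
# Gesture fixtures
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GestureFixtureSpec:
    """Study design of the gesture experiment (2 x 6 x 15 x 3 = 540)."""

    n_participants: int = 15
    n_gestures: int = 6
    n_postures: int = 3
    n_repetitions: int = 2
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    noise_sd: float = 0.03          # gyro rest noise, rad/s per axis
    acc_noise_sd: float = 0.05      # accelerometer noise, m/s² per axis
    base_amplitude: float = 2.0     # peak total angular velocity, rad/s
    seed: int = 0

    @property
    def total_samples(self) -> int:
        return (self.n_repetitions * self.n_gestures
                * self.n_participants * self.n_postures)


@dataclass(frozen=True)
class GestureSample:
    recording: InertialRecording
    prompt_time_s: float
    label: GestureLabel
    participant: int
    posture: int


# Per-finger gyro-axis mixing (x, y, z); adjacent fingers overlap.
_FINGER_MIX = {
    "index": np.array([0.90, 0.35, 0.25]),
    "middle": np.array([0.65, 0.65, 0.30]),
    "ring": np.array([0.35, 0.90, 0.40]),
}


def _rotation_matrix(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    """Small random 3D rotation (posture effect)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _tap_burst(t: np.ndarray, start_s: float, dur_s: float, amplitude: float,
               mix: np.ndarray, freq_hz: float) -> np.ndarray:
    """(n, 3) Gaussian-windowed oscillatory burst; phases offset per axis so
    the magnitude follows the envelope rather than collapsing at zero
    crossings."""
    center = start_s + dur_s / 2.0
    sigma = dur_s / 5.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    env[(t < start_s) | (t > start_s + dur_s)] = 0.0
    phase = 2 * np.pi * freq_hz * (t - start_s)
    osc = np.column_stack([np.sin(phase), np.cos(phase),
                           np.sin(phase + np.pi / 3)])
    return amplitude * env[:, None] * (osc * mix[None, :])


def gen_gesture_sample(label: GestureLabel, spec: GestureFixtureSpec,
                       rng: np.random.Generator, participant_gain: float = 1.0,
                       posture_rot: Optional[np.ndarray] = None,
                       participant: int = 0, posture: int = 0) -> GestureSample:
    """One prompt-triggered recording containing the requested gesture."""
    fs = spec.sampling_rate_hz
    duration_s = 4.0
    prompt_s = 0.4
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if posture_rot is None:
        posture_rot = np.eye(3)

    gyr = rng.normal(0.0, spec.noise_sd, size=(n, 3))
    delay = rng.uniform(0.3, 0.8)
    gstart = prompt_s + delay
    freq = rng.uniform(4.0, 7.0)
    amp = spec.base_amplitude * participant_gain * rng.uniform(0.85, 1.15)
    mix = _FINGER_MIX[label.finger]

    if label.taps == "single":
        dur = rng.uniform(0.35, 0.50)
        gyr += _tap_burst(t, gstart, dur, amp, mix, freq)
    else:
        d1 = rng.uniform(0.28, 0.38)
        d2 = rng.uniform(0.28, 0.38)
        gap = 0.120
        second = amp * rng.uniform(0.5, 1.0)
        gyr += _tap_burst(t, gstart, d1, amp, mix, freq)
        gyr += _tap_burst(t, gstart + d1 + gap, d2, second, mix, freq)

    gyr = gyr @ posture_rot.T

    # accelerometer: gravity along (rotated) z + movement transient + noise
    gvec = posture_rot @ np.array([0.0, 0.0, GRAVITY])
    acc = np.tile(gvec, (n, 1)) + rng.normal(0.0, spec.acc_noise_sd, size=(n, 3))
    acc += 1.5 * np.gradient(gyr, axis=0) * fs / 50.0

    return GestureSample(
        recording=InertialRecording(fs, t, acc[:, 0], acc[:, 1], acc[:, 2],
                                    gyr[:, 0], gyr[:, 1], gyr[:, 2]),
        prompt_time_s=prompt_s, label=label,
        participant=participant, posture=posture)


def gen_gesture_dataset(spec: GestureFixtureSpec = GestureFixtureSpec()
                        ) -> List[GestureSample]:
    """The full labeled dataset in the study's factorial design."""
    rng = np.random.default_rng(spec.seed)
    participant_gains = rng.lognormal(mean=0.0, sigma=0.15,
                                      size=spec.n_participants)
    samples: List[GestureSample] = []
    for p in range(spec.n_participants):
        posture_rots = [_rotation_matrix(rng, np.deg2rad(15.0))
                        for _ in range(spec.n_postures)]
        for posture in range(spec.n_postures):
            for code in range(1, spec.n_gestures + 1):
                for _rep in range(spec.n_repetitions):
                    samples.append(gen_gesture_sample(
                        GestureLabel.from_code(code), spec, rng,
                        participant_gain=participant_gains[p],
                        posture_rot=posture_rots[posture],
                        participant=p, posture=posture))
    return samples


def canonical_tap_template(fs: float = DEFAULT_SAMPLING_RATE_HZ
                           ) -> MagnitudeSeries:
    """Noise-free gyroscope-magnitude profile of one single index tap; the
    stored reference the DTW gate compares windows against."""
    dur = 0.32
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    burst = _tap_burst(t, 0.0, dur, 2.0, _FINGER_MIX["index"], 5.5)
    return MagnitudeSeries(np.linalg.norm(burst, axis=1), fs)


def circular_wrist_surrogate(fs: float = DEFAULT_SAMPLING_RATE_HZ,
                             duration_s: float = 2.8,
                             seed: int = 0) -> MagnitudeSeries:
    """Slow 1 Hz circular wrist movement: sustained rotation the gate must
    reject despite its amplitude reaching gesture levels."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    gyr = np.column_stack([
        1.2 * np.sin(2 * np.pi * 1.0 * t),
        1.2 * np.cos(2 * np.pi * 1.0 * t),
        0.3 * np.sin(2 * np.pi * 1.0 * t + 0.5),
    ]) + rng.normal(0.0, 0.03, size=(n, 3))
    return MagnitudeSeries(np.linalg.norm(gyr, axis=1), fs)


# ---------------------------------------------------------------------
# Audio fixtures
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class AudioClassDef:
    """Generator parameters of one audible-activity class."""

    name: str
    semantic_position: str
    mobile: bool
    centroid: Optional[Tuple[float, float, float]]
    band_centers_hz: Tuple[float, ...]
    band_widths_hz: Tuple[float, ...]
    band_gains: Tuple[float, ...]
    am_rate_hz: float = 0.0
    am_depth: float = 0.0
    tone_hz: float = 0.0
    tone_level: float = 0.0


# Water-noise envelope shared verbatim by sink and shower: the deliberately
# sound-confusable, direction-separable pair.
_WATER_BANDS = dict(band_centers_hz=(1200.0, 3200.0, 5200.0),
                    band_widths_hz=(900.0, 1400.0, 1600.0),
                    band_gains=(1.0, 0.8, 0.45))

AUDIO_CLASSES: Tuple[AudioClassDef, ...] = (
    AudioClassDef("runningWaterSink", "BATH", False, (0.80, -0.40, 0.45),
                  **_WATER_BANDS),
    AudioClassDef("blenderWorking", "KIT", False, (-0.70, 0.50, 0.50),
                  band_centers_hz=(180.0, 360.0, 720.0, 2400.0),
                  band_widths_hz=(60.0, 80.0, 120.0, 900.0),
                  band_gains=(1.0, 0.8, 0.6, 0.35),
                  tone_hz=175.0, tone_level=0.4),
    AudioClassDef("walkingSteps", "ANY", True, None,
                  band_centers_hz=(120.0, 320.0),
                  band_widths_hz=(90.0, 180.0),
                  band_gains=(1.0, 0.5),
                  am_rate_hz=2.0, am_depth=0.35),
    AudioClassDef("runningWaterBathSink", "BATH", False, (0.50, 0.60, -0.60),
                  band_centers_hz=(900.0, 2400.0, 4400.0),
                  band_widths_hz=(700.0, 1200.0, 1500.0),
                  band_gains=(1.0, 0.9, 0.6)),
    AudioClassDef("runningWaterShower", "BATH", False, (-0.60, -0.60, 0.50),
                  **_WATER_BANDS),
    AudioClassDef("flushingToilet", "BATH", False, (0.61, 0.49, 0.60),
                  band_centers_hz=(500.0, 1500.0, 3000.0),
                  band_widths_hz=(350.0, 800.0, 1100.0),
                  band_gains=(1.0, 0.7, 0.4),
                  am_rate_hz=0.5, am_depth=0.25),
    AudioClassDef("door", "LIV", False, (0.00, -0.90, 0.40),
                  band_centers_hz=(150.0, 600.0),
                  band_widths_hz=(100.0, 400.0),
                  band_gains=(1.0, 0.45),
                  am_rate_hz=1.2, am_depth=0.35),
    AudioClassDef("brushingTeeth", "ANY", True, None,
                  band_centers_hz=(2000.0, 4500.0),
                  band_widths_hz=(900.0, 1400.0),
                  band_gains=(1.0, 0.7),
                  am_rate_hz=4.0, am_depth=0.35),
)

UNKNOWN_CLASSES: Tuple[AudioClassDef, ...] = (
    AudioClassDef("ringingTelephone", "ANY", True, None,
                  band_centers_hz=(1150.0,), band_widths_hz=(80.0,),
                  band_gains=(1.0,), am_rate_hz=1.5, am_depth=0.4,
                  tone_hz=1200.0, tone_level=0.8),
    AudioClassDef("typingOnKeyboard", "ANY", True, None,
                  band_centers_hz=(6500.0,), band_widths_hz=(1200.0,),
                  band_gains=(1.0,), am_rate_hz=6.0, am_depth=0.4),
    AudioClassDef("teapotWhistling", "ANY", True, None,
                  band_centers_hz=(2850.0,), band_widths_hz=(60.0,),
                  band_gains=(1.0,), tone_hz=2800.0, tone_level=0.9),
)


@dataclass(frozen=True)
class AudioFixtureSpec:
    """Study design of the audio experiment: 8 classes x 10 clips."""

    samples_per_class: int = 10
    clip_s: Tuple[float, float] = (2.5, 5.2)
    n_unknown_classes: int = 3
    sampling_rate_hz: int = 16_000
    target_rms: float = 0.25
    direction_spread: float = 0.18   # max offset from the class centroid
    seed: int = 0


@dataclass
class AudioTrainingSet:
    clips: Dict[str, List[AudioClip]]
    directions: Dict[str, List[np.ndarray]]
    class_defs: Dict[str, AudioClassDef]

    @property
    def n_samples(self) -> int:
        return sum(len(v) for v in self.clips.values())


@dataclass(frozen=True)
class PlantedEvent:
    label: str
    start_s: float
    end_s: float
    direction: np.ndarray
    known: bool


@dataclass
class ContinuousSequence:
    stream: AudioClip
    events: List[PlantedEvent]


def _synth_clip(cdef: AudioClassDef, duration_s: float, fs: int,
                target_rms: float, rng: np.random.Generator) -> np.ndarray:
    """Band-shaped Gaussian noise (+ optional tone), shallow AM, fixed RMS."""
    n = int(round(duration_s * fs))
    noise = rng.normal(size=n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    for c, w, g in zip(cdef.band_centers_hz, cdef.band_widths_hz,
                       cdef.band_gains):
        gain += g * np.exp(-0.5 * ((freqs - c) / w) ** 2)
    x = np.fft.irfft(spec * gain, n=n)
    if cdef.tone_level > 0:
        t = np.arange(n) / fs
        x = x + cdef.tone_level * np.std(x) / 0.7 * np.sin(
            2 * np.pi * cdef.tone_hz * t + rng.uniform(0, 2 * np.pi))
    if cdef.am_depth > 0:
        t = np.arange(n) / fs
        am = 1.0 - cdef.am_depth * 0.5 * (
            1 + np.sin(2 * np.pi * cdef.am_rate_hz * t
                       + rng.uniform(0, 2 * np.pi)))
        x = x * am
    rms = np.sqrt(np.mean(x ** 2))
    x = x * (target_rms / rms) * rng.uniform(0.9, 1.1)
    return np.clip(x, -1.0, 1.0)


def _sample_direction(cdef: AudioClassDef, spread: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Fixed sources: centroid + offset of norm <= spread; mobile: random
    unit vector."""
    if cdef.mobile or cdef.centroid is None:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    offset = rng.normal(size=3)
    offset *= rng.uniform(0, spread) / np.linalg.norm(offset)
    return np.asarray(cdef.centroid) + offset


def gen_audio_dataset(spec: AudioFixtureSpec = AudioFixtureSpec()
                      ) -> AudioTrainingSet:
    """Training clips + directions for the 8 home-activity classes."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    clips: Dict[str, List[AudioClip]] = {}
    dirs: Dict[str, List[np.ndarray]] = {}
    for cdef in AUDIO_CLASSES:
        clips[cdef.name] = []
        dirs[cdef.name] = []
        for _ in range(spec.samples_per_class):
            dur = rng.uniform(*spec.clip_s)
            clips[cdef.name].append(AudioClip(
                _synth_clip(cdef, dur, fs, spec.target_rms, rng), fs,
                beamformed=True))
            dirs[cdef.name].append(_sample_direction(
                cdef, spec.direction_spread, rng))
    return AudioTrainingSet(clips=clips, directions=dirs,
                            class_defs={c.name: c for c in AUDIO_CLASSES})


def gen_continuous_sequences(spec: AudioFixtureSpec = AudioFixtureSpec(),
                             n_sequences: int = 5) -> List[ContinuousSequence]:
    """Unsegmented streams: every trained class once per sequence, plus the
    unknown sounds, separated by silence below the gate's active level."""
    rng = np.random.default_rng(spec.seed + 1)
    fs = spec.sampling_rate_hz
    unknown = UNKNOWN_CLASSES[: spec.n_unknown_classes]
    sequences: List[ContinuousSequence] = []
    for _ in range(n_sequences):
        order = list(AUDIO_CLASSES) + list(unknown)
        rng.shuffle(order)
        pieces: List[np.ndarray] = []
        events: List[PlantedEvent] = []
        cursor = 0

        def _silence(dur_s: float) -> np.ndarray:
            return rng.normal(0.0, 0.005, size=int(round(dur_s * fs)))

        pieces.append(_silence(rng.uniform(1.0, 1.6)))
        cursor += len(pieces[-1])
        for cdef in order:
            dur = rng.uniform(*spec.clip_s)
            x = _synth_clip(cdef, dur, fs, spec.target_rms, rng)
            events.append(PlantedEvent(
                label=cdef.name, start_s=cursor / fs,
                end_s=(cursor + len(x)) / fs,
                direction=_sample_direction(cdef, spec.direction_spread, rng),
                known=cdef in AUDIO_CLASSES))
            pieces.append(x)
            cursor += len(x)
            pieces.append(_silence(rng.uniform(1.0, 1.6)))
            cursor += len(pieces[-1])
        sequences.append(ContinuousSequence(
            stream=AudioClip(np.concatenate(pieces), fs, beamformed=True),
            events=events))
    return sequences
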