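"""Sound-event detection by energy hysteresis and MFCC extraction.

The annotator listens continuously. A per-frame energy envelope in [0, 1] is
compared against two levels: recording opens when energy rises above
mu_active (0.45) and closes when it falls below mu_inactive (0.30) or when
the event reaches the 5.20 s cap. Gated clips are described by 13
mel-frequency cepstral coefficients per 25 ms frame (10 ms step, 512-point
FFT) for the per-class hidden Markov models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.fftpack import dct
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "GateConfig",
    "SoundEvent",
    "read_wav",
    "write_wav",
    "energy_envelope",
    "gate",
    "extract_events",
    "mfcc",
]

CLASSIFIER_RATE_HZ = 16_000


@dataclass(frozen=True)
class AudioClip:
    """PCM audio in [-1, 1]; mono or 7-channel (microphone array).

    ``beamformed`` marks a single channel produced by combining the array
    channels; classification always consumes mono.
    """

    samples: np.ndarray          # (n,) mono or (n, 7)
    sampling_rate_hz: int = CLASSIFIER_RATE_HZ
    beamformed: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 2 and s.shape[1] == 1:
            s = s[:, 0]
        if s.ndim == 2 and s.shape[1] != 7:
            raise ValueError("multi-channel clips must have 7 channels")
        if s.ndim > 2:
            raise ValueError("samples must be (n,) or (n, 7)")
        object.__setattr__(self, "samples", s)

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    def mono(self) -> "AudioClip":
        """Mono view: channel mean stands in for the array's beamformed feed."""
        if self.samples.ndim == 1:
            return self
        return AudioClip(self.samples.mean(axis=1), self.sampling_rate_hz,
                         beamformed=True)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class GateConfig:
    """Hysteresis gate levels and limits.

    mu_active / mu_inactive: energy levels that open/close recording.
    max_clip_s: hard cap on one event (average audible-activity length).
    frame_ms: energy-envelope frame length.
    reference_rms: full-scale RMS mapped to energy 1.0.
    """

    mu_active: float = 0.45
    mu_inactive: float = 0.30
    max_clip_s: float = 5.20
    frame_ms: float = 64.0
    reference_rms: float = 0.35

    def __post_init__(self) -> None:
        if not self.mu_inactive < self.mu_active:
            raise ValueError("mu_inactive must be < mu_active")
        if self.max_clip_s <= 0:
            raise ValueError("max_clip_s must be positive")


@dataclass(frozen=True)
class SoundEvent:
    """A gated clip with its direction, time bounds and energy trace."""

    clip: AudioClip
    direction: np.ndarray
    start_s: float
    end_s: float
    energy_trace: np.ndarray
    stop_reason: str = "quiet"

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction",
                           np.asarray(self.direction, dtype=float))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_wav(path) -> AudioClip:
    """Read 16-bit PCM WAV into floats in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        samples = data.astype(float) / np.iinfo(data.dtype).max
    return AudioClip(samples, int(rate))


def write_wav(clip: AudioClip, path) -> None:
    """Write as 16-bit PCM."""
    data = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sampling_rate_hz, (data * 32767).astype(np.int16))


def _frame_rms(x: np.ndarray, frame_len: int) -> np.ndarray:
    n_frames = max(1, len(x) // frame_len) if len(x) >= frame_len else 1
    if len(x) < frame_len:
        return np.sqrt(np.mean(x ** 2, keepdims=True))
    trimmed = x[: n_frames * frame_len].reshape(n_frames, frame_len)
    return np.sqrt((trimmed ** 2).mean(axis=1))


def energy_envelope(clip: AudioClip, cfg: GateConfig = GateConfig()) -> np.ndarray:
    """Per-frame energy in [0, 1]: frame RMS / reference_rms, clipped.

    The array feed is reduced to mono (channel mean) first.
    """
    x = clip.mono().samples
    frame_len = max(1, int(round(cfg.frame_ms / 1000.0 * clip.sampling_rate_hz)))
    rms = _frame_rms(x, frame_len)
    return np.clip(rms / cfg.reference_rms, 0.0, 1.0)


def gate(energy_trace: np.ndarray,
         cfg: GateConfig = GateConfig()) -> List[Tuple[int, int, str]]:
    """Hysteresis gating on a per-frame energy trace.

    Opens at the first frame above mu_active; closes at the first frame
    below mu_inactive (stop_reason 'quiet') or when the event reaches
    max_clip_s (stop_reason 'max_len'). After closing, the gate re-arms only
    once energy has dropped below mu_inactive, so a single long loud sound
    yields exactly one capped event. Frames that never exceed mu_active
    produce nothing. Returns (start_frame, end_frame_exclusive, stop_reason).
    """
    e = np.asarray(energy_trace, dtype=float)
    frame_s = cfg.frame_ms / 1000.0
    max_frames = max(1, int(round(cfg.max_clip_s / frame_s)))
    events: List[Tuple[int, int, str]] = []
    state = "idle"   # idle -> recording -> cooldown -> idle
    start = 0
    for i, v in enumerate(e):
        if state == "idle":
            if v > cfg.mu_active:
                state, start = "recording", i
        elif state == "recording":
            if v < cfg.mu_inactive:
                events.append((start, i, "quiet"))
                state = "idle"
            elif i - start + 1 >= max_frames:
                events.append((start, start + max_frames, "max_len"))
                state = "cooldown"
        elif state == "cooldown":
            if v < cfg.mu_inactive:
                state = "idle"
    if state == "recording":
        events.append((start, min(len(e), start + max_frames),
                       "max_len" if len(e) - start >= max_frames else "quiet"))
    return events


def extract_events(clip: AudioClip, cfg: GateConfig = GateConfig(),
                   directions=None) -> List[SoundEvent]:
    """Gate a continuous stream and cut SoundEvents out of it.

    ``directions`` optionally supplies one 3-vector per detected event (in
    order); otherwise the zero vector is attached. Event sample bounds come
    from the frame grid, except that max-length events are cut to exactly
    max_clip_s worth of samples.
    """
    env = energy_envelope(clip, cfg)
    frame_len = max(1, int(round(cfg.frame_ms / 1000.0 * clip.sampling_rate_hz)))
    fs = clip.sampling_rate_hz
    events = []
    for k, (f0, f1, reason) in enumerate(gate(env, cfg)):
        s0 = f0 * frame_len
        if reason == "max_len":
            s1 = s0 + int(round(cfg.max_clip_s * fs))
        else:
            s1 = min(len(clip.samples), f1 * frame_len)
        d = (np.asarray(directions[k], dtype=float)
             if directions is not None else np.zeros(3))
        events.append(SoundEvent(
            clip=AudioClip(clip.samples[s0:s1], fs, beamformed=clip.beamformed),
            direction=d, start_s=s0 / fs, end_s=s1 / fs,
            energy_trace=env[f0:f1], stop_reason=reason))
    return events


# --- MFCC -------------------------------------------------------------
# Parameters of the classification front-end: 25 ms window, 10 ms step,
# 13 cepstra, 512-point FFT; 26 mel filters over 0..fs/2, pre-emphasis
# 0.97, sinusoidal liftering (L=22), and c0 replaced by the log frame
# energy. Frame count is floor((T - 25 ms) / 10 ms) + 1 (no end padding).

MFCC_WINDOW_MS = 25.0
MFCC_STEP_MS = 10.0
MFCC_NUM_CEPSTRA = 13
MFCC_NFFT = 512
MFCC_NUM_FILTERS = 26
MFCC_PREEMPH = 0.97
MFCC_LIFTER = 22


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int = MFCC_NUM_FILTERS, nfft: int = MFCC_NFFT,
                   fs: int = CLASSIFIER_RATE_HZ) -> np.ndarray:
    """(n_filters, nfft//2 + 1) triangular filters, mel-spaced over 0..fs/2."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_filters + 2)
    bins = np.floor((nfft + 1) * _mel_to_hz(mel_pts) / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for j in range(n_filters):
        l, c, r = bins[j], bins[j + 1], bins[j + 2]
        for i in range(l, c):
            fb[j, i] = (i - l) / max(1, c - l)
        for i in range(c, r):
            fb[j, i] = (r - i) / max(1, r - c)
    return fb


def mfcc(clip: AudioClip) -> np.ndarray:
    """(n_frames, 13) MFCC matrix of a mono clip at 16 kHz."""
    mono = clip.mono()
    if mono.sampling_rate_hz != CLASSIFIER_RATE_HZ:
        raise ValueError("classification path requires 16 kHz audio")
    fs = mono.sampling_rate_hz
    win = int(round(MFCC_WINDOW_MS / 1000.0 * fs))    # 400
    step = int(round(MFCC_STEP_MS / 1000.0 * fs))     # 160
    x = mono.samples
    if len(x) < win:
        raise ValueError("clip shorter than one analysis window")
    x = np.append(x[0], x[1:] - MFCC_PREEMPH * x[:-1])
    n_frames = 1 + (len(x) - win) // step
    idx = np.arange(win)[None, :] + step * np.arange(n_frames)[:, None]
    frames = x[idx]
    energy = (frames ** 2).sum(axis=1)
    energy = np.where(energy == 0, np.finfo(float).eps, energy)
    spec = np.abs(np.fft.rfft(frames, n=MFCC_NFFT, axis=1))
    pow_spec = (spec ** 2) / MFCC_NFFT
    fb = mel_filterbank(fs=fs)
    feat = pow_spec @ fb.T
    feat = np.where(feat == 0, np.finfo(float).eps, feat)
    ceps = dct(np.log(feat), type=2, axis=1, norm="ortho")[:, :MFCC_NUM_CEPSTRA]
    n = np.arange(MFCC_NUM_CEPSTRA)
    lift = 1 + (MFCC_LIFTER / 2.0) * np.sin(np.pi * n / MFCC_LIFTER)
    ceps = ceps * lift
    ceps[:, 0] = np.log(energy)
    return ceps
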