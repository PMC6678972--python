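# Methods

`selflabel` implements two semi-automated activity-labeling pipelines — a
smartwatch-gesture answer recognizer and an audible-home-activity annotator
— together with synthetic data generators that emulate the study designs
the pipelines were conceived for. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## 1. Gesture answer recognition

### Signal model

A recording is a 6-channel IMU stream (3-axis accelerometer in m/s²,
3-axis gyroscope in rad/s) from a wrist-worn device; the X axis points
along the arm. The pipeline operates on prompt-triggered windows: when the
system asks a labeling question, the user answers with one of six subtle
thumb-to-finger taps (single/double × index/middle/ring, coded 1–6).

Stages, in order:

1. **Gravity removal.** Acceleration channels are de-trended by
   subtracting a low-pass gravity estimate: first-order Butterworth,
   default cutoff 0.3 Hz, applied forward–backward (zero phase lag).
   Gravity is quasi-DC while tap transients live above a few Hz, so a
   gentle first-order filter suffices. Note that subtraction with a
   non-ideal filter is only exactly idempotent on components where the
   filter response is 0 or 1 (e.g. the DC gravity vector itself); on
   broadband content a second application removes a further sliver of
   low-frequency energy.
2. **Capture window.** The slice `[prompt, prompt + max_gesture + pad]`
   with `pad = 1.5 s` for the user's reaction time and
   `max_gesture = 1.3 s`.
3. **DTW presence gate.** The total angular velocity (Euclidean magnitude
   of the three gyroscope axes — orientation-invariant) is compared
   against a stored single-tap template by sliding the template across the
   window and taking the minimum dynamic-time-warping distance,
   normalized by template length. Classic DTW: absolute-difference local
   cost, full warping window, symmetric steps. The acceptance threshold
   (default 0.35 per template sample) was calibrated once on the synthetic
   fixtures so that ≥ 94% of true gesture windows pass while sustained
   movements such as a slow circular wrist rotation — which reaches
   gesture-level amplitude but has the wrong shape — are rejected.
4. **Boundary detection.** The magnitude signal is compressed into
   non-overlapping 240 ms blocks (block mean; a trailing partial block is
   averaged as-is so late gestures stay detectable). A block above the
   high threshold (0.4 rad/s) flags a candidate; the segment spans from
   the first to the last high block, extended outward while blocks stay
   above the low threshold (0.15 rad/s). Both thresholds are empirical
   levels, configurable. Because a 240 ms block grid cannot express the
   sub-block duration rules, the start/end are then refined to the raw
   low-threshold crossings inside the boundary blocks. Segments shorter
   than 200 ms or longer than 1300 ms are rejected (`too_short` /
   `too_long`; absence of any high block is `no_peak`); rejection is a
   value, and the caller prompts the user to repeat the gesture. An
   isolated terminal spike — a run above 0.4 rad/s within 220 ms of a
   boundary, separated from the gesture body by genuinely quiet
   (below-low) blocks — is trimmed before the final length check. The
   quiet-separation requirement is what distinguishes a sporadic end peak
   from the second burst of a double tap, which is bridged by above-low
   blocks.
5. **Features.** From each trimmed segment, 14 derived series (per
   sensor: X, Y, Z, XY = √(x²+y²), XZ, YZ, XYZ) each yield seven order
   statistics — mean, max, min, population SD, and the three quartiles
   (linear interpolation) — giving 98 time-domain features; the same
   seven statistics of the one-sided unnormalized FFT magnitude spectrum
   (DC bin included) give 98 spectral features; and each raw component
   contributes a signed and an absolute trapezoidal area under the curve
   (net vs total excursion), 12 more. Total: 208, in a frozen canonical
   order versioned with every persisted model.
6. **Normalization and classification.** Per-feature min–max scaling to
   [−1, 1] fitted on training data (constant features map to 0; unseen
   values are clipped) feeds a kernel SVM. Two configurations: RBF kernel
   with C = 4, γ = 0.0078125 (default), and an SMO-style polynomial-kernel
   machine with C = 11, degree 1. Multiclass is one-vs-one; ties resolve
   through the library's deterministic aggregated pairwise confidences.

Evaluation is stratified tenfold cross-validation with per-class precision
TP/(TP+FP) computed from the pooled confusion matrix and macro-averaged.
Pooling (rather than per-fold averaging) keeps small per-fold class counts
from producing undefined precisions.

### Gesture fixtures

Each synthetic sample is rest-level gyroscope noise (SD 0.03 rad/s per
axis) plus one or two Gaussian-windowed oscillatory bursts whose per-axis
amplitude mixture encodes the finger; phases are offset across axes so the
magnitude tracks the envelope. Singles last 0.35–0.50 s; doubles are two
0.28–0.38 s bursts separated by a 120 ms gap, with the second burst's
amplitude jittered down to 50–100% of the first, so weak doubles resemble
singles — the dominant confusion in practice. Participants contribute
log-normal amplitude factors (σ = 0.15), postures small random axis
rotations (≤ 15°); the accelerometer carries a posture-rotated gravity
vector plus movement transients. The full design is 15 participants ×
6 gestures × 3 postures × 2 repetitions = 540 samples, deterministic under
a seed. What passing tests show: the pipeline's rules and the classifier's
capacity to recover the planted class structure at realistic overlap. What
they do not show: robustness to real tremor, sensor bias, orientation
drift, or between-user waveform idiosyncrasies, all of which are richer
than amplitude/rotation effects.

## 2. Audible-home-activity annotation

### Event detection

A per-frame energy envelope (frame RMS over 64 ms frames, divided by a
reference level of 0.35 full-scale RMS, clipped to [0, 1]) is gated with
hysteresis: recording opens at the first frame above μ_active = 0.45 and
closes at the first frame below μ_inactive = 0.30 ("quiet") or at the
5.20 s cap ("max_len"); sounds that never exceed μ_active are ignored.
After any close the gate re-arms only once energy drops below μ_inactive,
so one long loud sound yields exactly one capped event. Max-length events
are cut at sample resolution to exactly 5.20 s. The energy normalization
(frame length and reference level) is this package's definition — the
upstream array firmware's exact formula is not public — chosen to
reproduce the documented hysteresis semantics at the printed levels.

### Classification and decision engine

Events are described by 13 MFCCs per frame: 25 ms window, 10 ms step,
512-point FFT, 26 mel filters over 0–8 kHz, pre-emphasis 0.97, DCT-II
(orthonormal), sinusoidal liftering L = 22, and the 0-th coefficient
replaced by the log frame energy. Frame count is ⌊(T − 25 ms)/10 ms⌋ + 1
(no end padding). Each trained class holds a 4-state ergodic Gaussian HMM
(diagonal covariances, EM with a fixed seed) over those frames, plus a
spatial-direction centroid: fixed sources use the mean of their training
directions with a 0.2 rejection radius; mobile sources (walking steps,
brushing teeth) carry the sentinel centroid [0, 0, 0] with a 10,000
threshold, so distance never rejects them and they are judged by
likelihood alone — the sentinel mechanism, not a code branch.

An incoming event is scored under every model (per-frame mean
log-likelihood, a length-invariant scale). For the top class with
likelihood L and direction distance d:

| condition                    | verbose mode                  | silent mode      |
|------------------------------|-------------------------------|------------------|
| d > thc                      | open query "What was that sound?" | store unlabeled |
| d ≤ thc, L ≥ th_p            | auto-label                    | auto-label       |
| d ≤ thc, th_uc ≤ L < th_p    | confirm "Was that a ⟨X⟩ sound?" | store unlabeled |
| d ≤ thc, L < th_uc           | open query                    | store unlabeled  |

Boundary semantics: L = th_p auto-labels ("equal or higher"), L = th_uc
still confirms, d = thc is not rejected. The distance check precedes the
likelihood comparison. The thresholds have no universal scale; defaults
(th_p = −45, th_uc = −60) suit the synthetic fixtures, and
`calibrate_thresholds` derives them from training data — th_p just below
the 10th percentile of own-class scores, th_uc a configurable gap (10)
below. Open-query replies with unseen labels register an untrained class
shell; retraining is explicit, never automatic. Confirmations accept
"yes" or a corrected label; "Which sound?" triggers the playback hook and
a re-prompt; empty replies re-prompt up to a retry limit. Every labeled
event becomes a five-field record {activityName, audioChannel,
3DDirection, semanticPosition, timestamp} appended to a JSONL store;
semantic positions use the room vocabulary {LIV, KIT, BATH, ANY}.

### Audio fixtures

Eight home-activity classes × 10 clips of 2.5–5.2 s at 16 kHz: Gaussian
noise shaped by class-specific spectral envelopes (sums of Gaussian bumps
in frequency), optionally with a tone (blender hum, telephone/teapot
whistles) and shallow amplitude modulation (footsteps, brushing) — deep
enough to give the HMMs structure, shallow enough that frame energy never
dips below the closing threshold mid-event. Clip RMS is ~0.25 full scale
(energy ≈ 0.7); inter-event silence is at RMS 0.005 (energy ≈ 0.014).
Crucially, the sink and shower classes share one spectral envelope but sit
at well-separated direction centroids: they are sound-confusable and
direction-separable by construction, which is the regime where direction
information pays. Fixed-source directions are sampled within 0.18 of
their centroid (inside the 0.2 radius). Three unknown classes (ringing
telephone, typing, teapot whistling) have spectra far from every trained
class. Five continuous sequences each contain every trained class once
plus the unknowns, in random order with ≥ 1 s silence gaps.

End-to-end evaluation scores the final stored label per event against
ground truth over {8 trained classes + unknown}, with a truthful simulated
responder answering queries. Under the sound-only condition (equivalent to
making every class mobile) the sink/shower pair produces confident wrong
auto-labels; with direction those predictions are rejected and corrected
through queries — the mechanism by which direction raises end-to-end
accuracy. What passing tests show: the decision engine, gating, and
HMM-likelihood machinery behave as specified, and direction fusion
measurably helps when sounds are spectrally confusable. What they do not
show: performance on real room acoustics, reverberation, overlapping
sources, or direction-estimation error (directions are inputs here;
direction-of-arrival estimation is out of scope).

## 3. Numerical and design choices

- Sampling rates: 50 Hz IMU (consumer smartwatch range; the devices'
  true rates are not public), 16 kHz audio. Both configurable.
- DTW gate hop: the template slides in 5-sample steps (100 ms at 50 Hz) —
  finer placement changes the minimum negligibly because DTW itself
  absorbs alignment error.
- Trailing partial compression block: averaged as-is rather than dropped.
- SD convention: population (ddof = 0) everywhere; quartiles by linear
  interpolation. Both matched by the brute-force oracles in the tests.
- FFT features use the magnitude (not power) spectrum of the
  unnormalized transform.
- Degenerate inputs: empty series and single-class training data raise;
  segmentation rejections and silent-mode non-answers are values.
- HMM training: 25 EM iterations, diagonal covariances; per-class model
  banks serialize to JSON (start probabilities, transition matrix, means,
  covariance diagonals), so a bank is portable text.
- Problem sizes in the shipped evaluation: the full 540-sample gesture
  design, and 20 generator seeds × 55 events for the annotator comparison
  — sizes at which every estimate in the acceptance report is stable to
  well under a percentage point across seeds.

## 4. Known limitations

- The fixtures are statistical stand-ins, not recordings; all headline
  numbers in `results/acceptance.json` quantify recovery of planted
  structure, not field performance.
- The gesture templates and fixtures share a waveform family, so the DTW
  gate's measured acceptance is optimistic relative to real data.
- The energy-envelope definition, the likelihood-threshold calibration
  rule, and the AUC feature pair are this package's own concrete choices
  where the deployed systems' internals are unpublished; each is exposed
  as configuration.
- One fixture sample in 540 can be rejected at segmentation (`no_peak`)
  when a low-gain participant draw meets an unfavorable posture rotation;
  the classifier is trained and evaluated on accepted segments, as the
  deployed system would be.
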