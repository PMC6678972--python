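"""ISSA's core: per-class Gaussian HMMs, direction centroids, the decision
table, new-class registration and annotation records.

Each trained sound class holds a 4-state ergodic Gaussian HMM over 13-dim
MFCC frames plus a spatial-direction centroid. Fixed sources carry a 0.2
centroid radius; mobile sources (walking, brushing teeth) carry the sentinel
centroid [0, 0, 0] with a huge threshold (10,000) so they are judged by
likelihood alone. An incoming event is scored under every model; the top
class is rejected outright if the event's direction is farther than the
class threshold from the centroid, otherwise its per-frame mean
log-likelihood L is compared with the prediction threshold th_p and the
unknown-class threshold th_uc:

    dist > thc              -> open query  ("What was that sound?")
    L >= th_p               -> auto-label as the predicted class
    th_uc <= L < th_p       -> confirmation query ("Was that a <X> sound?")
    L < th_uc               -> open query

In silent mode the two query actions store the event unlabeled instead of
asking. Every labeled event becomes a five-field annotation record
{activityName, audioChannel, 3DDirection, semanticPosition, timestamp}
appended to a JSONL store.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .audio_frontend import SoundEvent, mfcc

__all__ = [
    "FIXED_SOURCE_RADIUS",
    "MOBILE_SOURCE_THRESHOLD",
    "MOBILE_SOURCE_CENTROID",
    "SoundClass",
    "DecisionConfig",
    "Action",
    "Decision",
    "AnnotationRecord",
    "AnnotationStore",
    "train_class",
    "score",
    "direction_distance",
    "decide",
    "calibrate_thresholds",
    "Annotator",
    "handle_response",
    "make_record",
    "run_pipeline",
]

FIXED_SOURCE_RADIUS = 0.2
MOBILE_SOURCE_THRESHOLD = 10_000.0
MOBILE_SOURCE_CENTROID = (0.0, 0.0, 0.0)
N_HMM_STATES = 4

#: Room-level location vocabulary (extensible).
SEMANTIC_POSITIONS = ("LIV", "KIT", "BATH", "ANY")


@dataclass
class SoundClass:
    """A trained (or shell) sound class.

    ``hmm`` is None for a freshly registered class that has not reached the
    minimum number of training samples yet.
    """

    name: str
    hmm: Optional[GaussianHMM]
    centroid: np.ndarray
    centroid_threshold: float
    n_training: int = 0
    mobile: bool = False
    semantic_position: str = "ANY"

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid_threshold <= 0:
            raise ValueError("centroid_threshold must be positive")
        if self.hmm is not None and self.hmm.n_components != N_HMM_STATES:
            raise ValueError(f"class HMM must have {N_HMM_STATES} states")

    @property
    def trained(self) -> bool:
        return self.hmm is not None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "centroid": self.centroid.tolist(),
            "centroid_threshold": self.centroid_threshold,
            "n_training": self.n_training,
            "mobile": self.mobile,
            "semantic_position": self.semantic_position,
            "hmm": None,
        }
        if self.hmm is not None:
            d["hmm"] = {
                "startprob": self.hmm.startprob_.tolist(),
                "transmat": self.hmm.transmat_.tolist(),
                "means": self.hmm.means_.tolist(),
                "covars": np.asarray([np.diag(c) for c in self.hmm.covars_]).tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SoundClass":
        hmm = None
        if d.get("hmm") is not None:
            h = d["hmm"]
            means = np.asarray(h["means"], dtype=float)
            hmm = GaussianHMM(n_components=N_HMM_STATES, covariance_type="diag",
                              init_params="", params="")
            hmm.startprob_ = np.asarray(h["startprob"], dtype=float)
            hmm.transmat_ = np.asarray(h["transmat"], dtype=float)
            hmm.means_ = means
            hmm.covars_ = np.asarray(h["covars"], dtype=float)
            hmm.n_features = means.shape[1]
        return cls(name=d["name"], hmm=hmm,
                   centroid=np.asarray(d["centroid"], dtype=float),
                   centroid_threshold=float(d["centroid_threshold"]),
                   n_training=int(d.get("n_training", 0)),
                   mobile=bool(d.get("mobile", False)),
                   semantic_position=d.get("semantic_position", "ANY"))


@dataclass(frozen=True)
class DecisionConfig:
    """Likelihood thresholds (per-frame mean log-likelihood) and query mode.

    th_p: at or above it the prediction is auto-labeled. th_uc: below it the
    sound is treated as an untrained class. Between the two the user is
    asked to confirm. Both are on a length-invariant scale; defaults suit
    the synthetic fixtures and should be calibrated per deployment
    (:func:`calibrate_thresholds`).
    """

    th_p: float = -45.0
    th_uc: float = -60.0
    mode: str = "verbose"
    max_retries: int = 3

    def __post_init__(self) -> None:
        if not self.th_uc < self.th_p:
            raise ValueError("th_uc must be < th_p")
        if self.mode not in ("verbose", "silent"):
            raise ValueError("mode must be 'verbose' or 'silent'")


class Action(str, Enum):
    AUTO_LABEL = "AUTO_LABEL"
    CONFIRM_QUERY = "CONFIRM_QUERY"
    OPEN_QUERY = "OPEN_QUERY"
    STORE_UNLABELED = "STORE_UNLABELED"


@dataclass(frozen=True)
class Decision:
    action: Action
    predicted: Optional[str] = None
    prompt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.action in (Action.AUTO_LABEL, Action.CONFIRM_QUERY):
            if self.predicted is None:
                raise ValueError(f"{self.action} requires a predicted label")


def train_class(name: str, mfcc_samples: Sequence[np.ndarray],
                directions: Sequence[np.ndarray], mobile: bool = False,
                seed: int = 0, semantic_position: str = "ANY",
                n_iter: int = 25) -> SoundClass:
    """Fit one class: a 4-state ergodic Gaussian HMM plus direction centroid.

    Fixed sources get centroid = mean of the training directions and the 0.2
    radius; mobile sources get the [0,0,0] sentinel with threshold 10,000.
    Requires at least 3 sample clips.
    """
    samples = [np.asarray(s, dtype=float) for s in mfcc_samples]
    if len(samples) < 3:
        raise ValueError("need at least 3 training clips per class")
    X = np.vstack(samples)
    lengths = [len(s) for s in samples]
    hmm = GaussianHMM(n_components=N_HMM_STATES, covariance_type="diag",
                      n_iter=n_iter, random_state=seed)
    hmm.fit(X, lengths)
    if mobile:
        centroid = np.asarray(MOBILE_SOURCE_CENTROID)
        threshold = MOBILE_SOURCE_THRESHOLD
    else:
        centroid = np.mean(np.asarray(directions, dtype=float), axis=0)
        threshold = FIXED_SOURCE_RADIUS
    return SoundClass(name=name, hmm=hmm, centroid=centroid,
                      centroid_threshold=threshold, n_training=len(samples),
                      mobile=mobile, semantic_position=semantic_position)


def score(models: Sequence[SoundClass],
          feats: np.ndarray) -> Tuple[str, Dict[str, float]]:
    """Per-frame mean log-likelihood under each trained class.

    Returns ``(best_name, {name: score})``; the argmax is deterministic
    (ties broken by model-name order) and invariant to list order.
    """
    trained = [m for m in models if m.trained]
    if not trained:
        raise ValueError("need at least one trained model")
    X = np.asarray(feats, dtype=float)
    scores = {m.name: float(m.hmm.score(X)) / len(X) for m in trained}
    best = max(sorted(scores), key=lambda k: scores[k])
    return best, scores


def direction_distance(d: np.ndarray, cls: SoundClass) -> float:
    """Euclidean distance from the event direction to the class centroid."""
    return float(np.linalg.norm(np.asarray(d, dtype=float) - cls.centroid))


def decide(best: str, L: float, dist: float, thc: float,
           cfg: DecisionConfig) -> Decision:
    """The annotator's decision table (total and deterministic).

    Verbose mode: (1) dist > thc rejects the prediction -> open query;
    (2) L >= th_p -> auto-label; (3) th_uc <= L < th_p -> confirmation
    query; (4) L < th_uc -> open query. Silent mode replaces both query
    actions with STORE_UNLABELED.
    """
    silent = cfg.mode == "silent"

    def query(action: Action, predicted=None, prompt=None) -> Decision:
        if silent:
            return Decision(Action.STORE_UNLABELED, predicted=predicted)
        return Decision(action, predicted=predicted, prompt=prompt)

    if dist > thc:
        return query(Action.OPEN_QUERY, prompt="What was that sound?")
    if L >= cfg.th_p:
        return Decision(Action.AUTO_LABEL, predicted=best)
    if L >= cfg.th_uc:
        return query(Action.CONFIRM_QUERY, predicted=best,
                     prompt=f"Was that a {best} sound?")
    return query(Action.OPEN_QUERY, prompt="What was that sound?")


def calibrate_thresholds(models: Sequence[SoundClass],
                         training_feats: Dict[str, Sequence[np.ndarray]],
                         percentile: float = 10.0, margin: float = 1.0,
                         gap: float = 10.0, mode: str = "verbose") -> DecisionConfig:
    """Derive th_p / th_uc from the training-score distribution.

    th_p is set just below the ``percentile``-th percentile of own-class
    per-frame log-likelihoods (so nearly all in-class sounds auto-label);
    th_uc sits ``gap`` below th_p.
    """
    by_name = {m.name: m for m in models if m.trained}
    own = []
    for name, clips in training_feats.items():
        m = by_name[name]
        own.extend(float(m.hmm.score(np.asarray(c))) / len(c) for c in clips)
    th_p = float(np.percentile(own, percentile)) - margin
    return DecisionConfig(th_p=th_p, th_uc=th_p - gap, mode=mode)


# --- Annotation records -------------------------------------------------

_FIELDS = ("activityName", "audioChannel", "3DDirection",
           "semanticPosition", "timestamp")


@dataclass(frozen=True)
class AnnotationRecord:
    """One five-field annotation: who/where/when a labeled sound happened.

    ``audio_channel`` is a reference to the stored audio (a relative WAV
    path, or the per-microphone waveform array reference).
    """

    activity_name: str
    audio_channel: object
    direction: Tuple[float, float, float]
    semantic_position: str
    timestamp: str

    def __post_init__(self) -> None:
        if not self.activity_name:
            raise ValueError("activityName must be non-empty")
        for f in ("audio_channel", "semantic_position", "timestamp"):
            if getattr(self, f) in (None, ""):
                raise ValueError(f"missing field: {f}")
        datetime.fromisoformat(str(self.timestamp).replace("Z", "+00:00"))
        object.__setattr__(self, "direction",
                           tuple(float(v) for v in self.direction))

    def to_dict(self) -> dict:
        return {
            "activityName": self.activity_name,
            "audioChannel": self.audio_channel,
            "3DDirection": list(self.direction),
            "semanticPosition": self.semantic_position,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationRecord":
        missing = [f for f in _FIELDS if f not in d]
        if missing:
            raise ValueError(f"missing field(s): {', '.join(missing)}")
        return cls(activity_name=d["activityName"],
                   audio_channel=d["audioChannel"],
                   direction=tuple(d["3DDirection"]),
                   semantic_position=d["semanticPosition"],
                   timestamp=d["timestamp"])


def make_record(label: str, clip_ref, direction, semantic_position: str,
                timestamp: str) -> AnnotationRecord:
    """Build the five-field record for one labeled sound event."""
    return AnnotationRecord(activity_name=label, audio_channel=clip_ref,
                            direction=tuple(np.asarray(direction, dtype=float)),
                            semantic_position=semantic_position,
                            timestamp=timestamp)


class AnnotationStore:
    """Append-only JSONL store, one record per line."""

    def __init__(self, path=None):
        self.path = path
        self._records: List[AnnotationRecord] = []

    def append(self, record: AnnotationRecord) -> None:
        self._records.append(record)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record.to_dict()) + "\n")

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> List[AnnotationRecord]:
        return list(self._records)

    @staticmethod
    def read(path) -> List[AnnotationRecord]:
        out = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    out.append(AnnotationRecord.from_dict(json.loads(line)))
        return out


# --- Interactive annotator ----------------------------------------------

class Annotator:
    """Holds the model bank, decision config and store; processes events.

    ``playback_hook`` is called when the user answers an open query with
    "Which sound?" (the deployed system replays the recorded clip).
    New labels register an untrained :class:`SoundClass` shell; shells start
    scoring only after an explicit retraining step (automatic retraining is
    out of scope).
    """

    def __init__(self, models: Sequence[SoundClass], cfg: DecisionConfig,
                 store: Optional[AnnotationStore] = None,
                 playback_hook: Optional[Callable] = None,
                 min_train_samples: int = 3):
        self.classes: Dict[str, SoundClass] = {m.name: m for m in models}
        self.cfg = cfg
        self.store = store if store is not None else AnnotationStore()
        self.playback_hook = playback_hook
        self.min_train_samples = min_train_samples
        self.pending: Dict[str, int] = {}

    def trained_models(self) -> List[SoundClass]:
        return [m for m in self.classes.values() if m.trained]

    def register_class(self, label: str, mobile: bool = False,
                       semantic_position: str = "ANY") -> SoundClass:
        """Create an untrained shell for a newly named sound class."""
        if label not in self.classes:
            self.classes[label] = SoundClass(
                name=label, hmm=None,
                centroid=np.asarray(MOBILE_SOURCE_CENTROID),
                centroid_threshold=MOBILE_SOURCE_THRESHOLD,
                mobile=mobile, semantic_position=semantic_position)
        self.pending[label] = self.pending.get(label, 0) + 1
        return self.classes[label]

    def process_event(self, event: SoundEvent, responder=None,
                      use_direction: bool = True,
                      timestamp: str = "1970-01-01T00:00:00Z",
                      clip_ref: object = "audioData"):
        """score -> (direction gate) -> decide -> handle the user response.

        Returns ``(decision, record_or_None, final_label_or_None)``.
        """
        feats = mfcc(event.clip)
        best, _scores = score(self.trained_models(), feats)
        cls = self.classes[best]
        if use_direction:
            dist = direction_distance(event.direction, cls)
            thc = cls.centroid_threshold
        else:
            # sound-only condition: equivalent to every class being mobile
            dist, thc = 0.0, MOBILE_SOURCE_THRESHOLD
        decision = decide(best, _scores[best], dist, thc, self.cfg)
        record, label = handle_response(self, decision, responder, event,
                                        timestamp=timestamp, clip_ref=clip_ref)
        return decision, record, label


def handle_response(annotator: Annotator, decision: Decision, responder,
                    event: SoundEvent, timestamp: str = "1970-01-01T00:00:00Z",
                    clip_ref: object = "audioData"):
    """Resolve a decision into an annotation record (or nothing).

    ``responder`` is ``callable(decision) -> str`` simulating or relaying
    the user's reply. Confirmations: "yes" keeps the predicted label, any
    other non-empty reply is taken as the correct label. Open queries:
    the reply is the label; "Which sound?" triggers the playback hook and a
    re-prompt. Unseen labels register a new class shell. Empty replies
    re-prompt up to ``cfg.max_retries`` times.
    """
    cfg = annotator.cfg
    if decision.action == Action.STORE_UNLABELED:
        return None, None
    if decision.action == Action.AUTO_LABEL:
        label = decision.predicted
    else:
        if responder is None:
            raise ValueError("a responder is required for query decisions")
        label = None
        for _ in range(cfg.max_retries + 1):
            reply = responder(decision)
            if reply is None or reply == "":
                continue
            if reply.strip().lower() == "which sound?":
                if annotator.playback_hook is not None:
                    annotator.playback_hook(event)
                continue
            if decision.action == Action.CONFIRM_QUERY and \
                    reply.strip().lower() in ("yes", "y"):
                label = decision.predicted
            else:
                label = reply.strip()
            break
        if label is None:
            raise ValueError("no usable reply after retries")
        if label not in annotator.classes:
            annotator.register_class(label)
    cls = annotator.classes[label]
    record = make_record(label, clip_ref, event.direction,
                         cls.semantic_position, timestamp)
    annotator.store.append(record)
    return record, label


def run_pipeline(events: Sequence[SoundEvent], truths: Sequence[str],
                 models: Sequence[SoundClass], cfg: DecisionConfig,
                 responder: Optional[Callable[[Decision, int], str]] = None,
                 use_direction: bool = True,
                 store: Optional[AnnotationStore] = None):
    """Annotate an event stream and tally a confusion matrix.

    ``truths`` holds one ground-truth label per event (labels outside the
    trained set fall into the "unknown" bucket). ``responder(decision, i)``
    supplies the simulated user's reply for event i; by default it answers
    truthfully (confirms correct predictions, provides the true label
    otherwise). Returns ``(records, confusion, accuracy)`` where the
    confusion matrix rows are true classes, columns are the system's final
    labels, over {trained classes + unknown}.
    """
    trained_names = [m.name for m in models if m.trained]
    if responder is None:
        def responder(decision: Decision, i: int) -> str:
            truth = truths[i]
            if decision.action == Action.CONFIRM_QUERY and \
                    decision.predicted == truth:
                return "yes"
            return truth

    annotator = Annotator(models, cfg, store=store)
    buckets = trained_names + ["unknown"]
    conf = pd.DataFrame(0, index=buckets, columns=buckets, dtype=int)

    def bucket(label: Optional[str]) -> str:
        return label if label in trained_names else "unknown"

    for i, (event, truth) in enumerate(zip(events, truths)):
        _, _, label = annotator.process_event(
            event, responder=lambda d, _i=i: responder(d, _i),
            use_direction=use_direction)
        conf.loc[bucket(truth), bucket(label)] += 1

    total = conf.to_numpy().sum()
    accuracy = float(np.trace(conf.to_numpy())) / total if total else math.nan
    return annotator.store.records(), conf, accuracy
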