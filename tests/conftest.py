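import numpy as np
import pytest

from selflabel import fixtures as fx
from selflabel import gesture_classifier as gc
from selflabel import gesture_features as gf
from selflabel import gesture_segmentation as gs
from selflabel import inertial_signals as isg


def run_gesture_pipeline(samples, seg_cfg=None):
    """Segment every sample; return (features, labels, rejections)."""
    seg_cfg = seg_cfg or gs.SegmentationConfig()
    feats, labels, rejections = [], [], []
    for s in samples:
        window = gs.capture_window(s.recording, s.prompt_time_s,
                                   seg_cfg.max_gesture_ms / 1000.0, seg_cfg)
        window = isg.remove_gravity(window)
        mag = isg.magnitude(window, "gyroscope")
        seg = gs.segment_window(window, mag, seg_cfg)
        if isinstance(seg, gs.Rejection):
            rejections.append((s.label, seg.reason))
        else:
            feats.append(gf.extract_features(seg))
            labels.append(s.label)
    return feats, labels, rejections


@pytest.fixture(scope="session")
def small_gesture_dataset():
    """Reduced factorial design (6 participants) for unit-level tests."""
    return fx.gen_gesture_dataset(fx.GestureFixtureSpec(n_participants=6, seed=7))


@pytest.fixture(scope="session")
def small_gesture_features(small_gesture_dataset):
    feats, labels, _ = run_gesture_pipeline(small_gesture_dataset)
    norm = gf.fit_normalizer(feats)
    X = gf.normalize_matrix(norm, feats)
    return X, labels, norm


@pytest.fixture(scope="session")
def small_gesture_model(small_gesture_features):
    X, labels, norm = small_gesture_features
    return gc.train(X, labels, gc.ClassifierConfig(seed=0), normalizer=norm)


@pytest.fixture(scope="session")
def full_gesture_dataset():
    """The complete 540-sample study design (acceptance-level tests)."""
    return fx.gen_gesture_dataset(fx.GestureFixtureSpec(seed=0))


@pytest.fixture(scope="session")
def full_gesture_features(full_gesture_dataset):
    feats, labels, rejections = run_gesture_pipeline(full_gesture_dataset)
    norm = gf.fit_normalizer(feats)
    X = gf.normalize_matrix(norm, feats)
    return X, labels, rejections


@pytest.fixture(scope="session")
def small_audio_training():
    """Reduced audio training set (4 clips/class) for unit-level tests."""
    return fx.gen_audio_dataset(fx.AudioFixtureSpec(samples_per_class=4, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
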