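import json

import numpy as np
import pytest
from hmmlearn.hmm import GaussianHMM

from selflabel import audio_frontend as af
from selflabel import fixtures as fx
from selflabel import sound_annotation as sa


def _known_hmm(mean_offset, seed):
    """A 4-state generator HMM with well-separated state means."""
    h = GaussianHMM(n_components=4, covariance_type="diag",
                    random_state=seed, init_params="", params="")
    h.startprob_ = np.full(4, 0.25)
    h.transmat_ = np.full((4, 4), 0.1) + np.eye(4) * 0.6
    rng = np.random.default_rng(seed)
    h.means_ = mean_offset + rng.normal(0, 1.0, size=(4, 13))
    h.covars_ = np.full((4, 13), 0.5)
    h.n_features = 13
    return h


def _sample_clips(h, n_clips, n_frames, seed):
    return [h.sample(n_frames, random_state=seed + i)[0]
            for i in range(n_clips)]


@pytest.fixture(scope="module")
def trained_pair():
    """Two classes trained on samples from known, separated generators."""
    gen_a = _known_hmm(0.0, seed=1)
    gen_b = _known_hmm(8.0, seed=2)
    clips_a = _sample_clips(gen_a, 30, 80, seed=100)
    clips_b = _sample_clips(gen_b, 30, 80, seed=200)
    dirs = [np.array([1.0, 0.0, 0.0])] * 30
    cls_a = sa.train_class("classA", clips_a, dirs, seed=0)
    cls_b = sa.train_class("classB", clips_b, dirs, seed=0)
    return (gen_a, gen_b), (cls_a, cls_b)


class TestTrainClass:
    def test_too_few_samples_rejected(self, rng):
        clips = [rng.normal(size=(50, 13)) for _ in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            sa.train_class("x", clips, [np.zeros(3)] * 2)

    def test_fixed_source_centroid_within_radius(self, small_audio_training):
        """Clustered training directions all fall within the 0.2 centroid
        radius, as with the deployed fixed sources."""
        train = small_audio_training
        name = "blenderWorking"
        feats = [af.mfcc(c) for c in train.clips[name]]
        cls = sa.train_class(name, feats, train.directions[name])
        assert not cls.mobile
        assert cls.centroid_threshold == 0.2
        for d in train.directions[name]:
            assert np.linalg.norm(d - cls.centroid) <= 0.2

    def test_mobile_source_sentinel(self, rng):
        clips = [rng.normal(size=(50, 13)) for _ in range(3)]
        cls = sa.train_class("walk", clips, [], mobile=True)
        np.testing.assert_array_equal(cls.centroid, [0.0, 0.0, 0.0])
        assert cls.centroid_threshold == 10_000

    def test_heldout_likelihood_separates_generators(self, trained_pair):
        """Held-out clips score higher under their own class's model than
        clips from the other generator do, in >= 95% of trials."""
        (gen_a, gen_b), (cls_a, _) = trained_pair
        wins = 0
        trials = 40
        for i in range(trials):
            own = gen_a.sample(80, random_state=1000 + i)[0]
            other = gen_b.sample(80, random_state=2000 + i)[0]
            wins += (cls_a.hmm.score(own) / len(own)
                     > cls_a.hmm.score(other) / len(other))
        assert wins / trials >= 0.95


class TestScore:
    def test_single_model_is_argmax(self, trained_pair, rng):
        _, (cls_a, _) = trained_pair
        best, scores = sa.score([cls_a], rng.normal(size=(40, 13)))
        assert best == "classA"
        assert set(scores) == {"classA"}

    def test_own_generator_ranked_first(self, trained_pair):
        (gen_a, gen_b), (cls_a, cls_b) = trained_pair
        clip = gen_a.sample(80, random_state=999)[0]
        best, _ = sa.score([cls_a, cls_b], clip)
        assert best == "classA"
        clip = gen_b.sample(80, random_state=998)[0]
        best, _ = sa.score([cls_b, cls_a], clip)
        assert best == "classB"

    def test_model_order_invariance(self, trained_pair, rng):
        _, (cls_a, cls_b) = trained_pair
        x = rng.normal(size=(60, 13))
        b1, s1 = sa.score([cls_a, cls_b], x)
        b2, s2 = sa.score([cls_b, cls_a], x)
        assert b1 == b2
        assert s1 == s2

    def test_no_trained_models_rejected(self):
        shell = sa.SoundClass("new", None, np.zeros(3), 10_000)
        with pytest.raises(ValueError, match="trained"):
            sa.score([shell], np.zeros((10, 13)))


class TestDirectionDistance:
    def test_centroid_distance_zero(self, trained_pair):
        _, (cls_a, _) = trained_pair
        assert sa.direction_distance(cls_a.centroid, cls_a) == 0.0

    def test_orthogonal_unit_vectors(self):
        cls = sa.SoundClass("c", None, np.array([1.0, 0, 0]), 0.2)
        assert sa.direction_distance(np.array([0.0, 1.0, 0.0]), cls) == \
            pytest.approx(np.sqrt(2))

    def test_mobile_class_never_rejected(self, rng):
        cls = sa.SoundClass("walk", None, np.zeros(3), 10_000, mobile=True)
        for _ in range(20):
            d = rng.uniform(-1, 1, size=3)
            assert sa.direction_distance(d, cls) < cls.centroid_threshold


def _expected_action(L, dist, thc, th_p, th_uc, mode):
    """Hand-enumerated truth table, written independently of decide()."""
    if dist > thc:
        base = "OPEN_QUERY"
    elif L >= th_p:
        return "AUTO_LABEL"
    elif L >= th_uc:
        base = "CONFIRM_QUERY"
    else:
        base = "OPEN_QUERY"
    return "STORE_UNLABELED" if mode == "silent" else base


class TestDecide:
    TH_P, TH_UC, THC = -40.0, -60.0, 0.2

    @pytest.mark.parametrize("mode", ["verbose", "silent"])
    @pytest.mark.parametrize("L", [-20.0, -40.0, -50.0, -60.0, -80.0])
    @pytest.mark.parametrize("dist", [0.0, 0.2, 0.3])
    def test_matches_truth_table(self, L, dist, mode):
        cfg = sa.DecisionConfig(th_p=self.TH_P, th_uc=self.TH_UC, mode=mode)
        decision = sa.decide("tap", L, dist, self.THC, cfg)
        assert decision.action.value == _expected_action(
            L, dist, self.THC, self.TH_P, self.TH_UC, mode)

    def test_boundary_semantics(self):
        cfg = sa.DecisionConfig(th_p=self.TH_P, th_uc=self.TH_UC)
        # L exactly at th_p auto-labels ("equal or higher")
        assert sa.decide("x", self.TH_P, 0.0, self.THC, cfg).action == \
            sa.Action.AUTO_LABEL
        # L exactly at th_uc still asks for confirmation
        assert sa.decide("x", self.TH_UC, 0.0, self.THC, cfg).action == \
            sa.Action.CONFIRM_QUERY
        # dist exactly at thc is not rejected
        assert sa.decide("x", self.TH_P, self.THC, self.THC, cfg).action == \
            sa.Action.AUTO_LABEL

    def test_prompts(self):
        cfg = sa.DecisionConfig(th_p=self.TH_P, th_uc=self.TH_UC)
        d = sa.decide("doorSlam", -50.0, 0.0, self.THC, cfg)
        assert d.prompt == "Was that a doorSlam sound?"
        d = sa.decide("doorSlam", -90.0, 0.0, self.THC, cfg)
        assert d.prompt == "What was that sound?"
        assert d.predicted is None

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="th_uc"):
            sa.DecisionConfig(th_p=-60.0, th_uc=-40.0)


def _event(direction=(1.0, 0.0, 0.0)):
    rng = np.random.default_rng(0)
    clip = af.AudioClip(rng.uniform(-0.3, 0.3, size=8000), 16_000)
    return af.SoundEvent(clip=clip, direction=np.asarray(direction),
                         start_s=0.0, end_s=0.5,
                         energy_trace=np.array([0.5]))


def _annotator(cfg=None):
    cls = sa.SoundClass("flushingToilet", None, np.array([0.61, 0.49, 0.60]),
                        0.2, semantic_position="BATH")
    return sa.Annotator([cls], cfg or sa.DecisionConfig())


class TestHandleResponse:
    def test_confirmed_yes_records_prediction(self):
        ann = _annotator()
        decision = sa.Decision(sa.Action.CONFIRM_QUERY,
                               predicted="flushingToilet",
                               prompt="Was that a flushingToilet sound?")
        record, label = sa.handle_response(ann, decision, lambda d: "yes",
                                           _event())
        assert label == "flushingToilet"
        assert record.semantic_position == "BATH"
        assert len(ann.store) == 1

    def test_open_query_registers_new_class(self):
        ann = _annotator()
        decision = sa.Decision(sa.Action.OPEN_QUERY,
                               prompt="What was that sound?")
        record, label = sa.handle_response(
            ann, decision, lambda d: "teapot whistling", _event())
        assert label == "teapot whistling"
        assert "teapot whistling" in ann.classes
        assert not ann.classes["teapot whistling"].trained

    def test_which_sound_invokes_playback_then_reprompts(self):
        played = []
        replies = iter(["Which sound?", "doorSlam"])
        ann = _annotator()
        ann.playback_hook = played.append
        decision = sa.Decision(sa.Action.OPEN_QUERY,
                               prompt="What was that sound?")
        record, label = sa.handle_response(ann, decision,
                                           lambda d: next(replies), _event())
        assert len(played) == 1
        assert label == "doorSlam"

    def test_empty_replies_exhaust_retries(self):
        ann = _annotator()
        decision = sa.Decision(sa.Action.OPEN_QUERY, prompt="?")
        with pytest.raises(ValueError, match="no usable reply"):
            sa.handle_response(ann, decision, lambda d: "", _event())

    def test_store_unlabeled_stores_nothing(self):
        ann = _annotator()
        decision = sa.Decision(sa.Action.STORE_UNLABELED)
        record, label = sa.handle_response(ann, decision, None, _event())
        assert record is None and label is None
        assert len(ann.store) == 0


class TestAnnotationRecord:
    def test_printed_flushing_toilet_record(self):
        """The canonical worked example: flushing toilet at a known
        direction and timestamp."""
        rec = sa.make_record("flushingToilet", "audioData",
                             [0.61, 0.49, 0.60], "BATH",
                             "2019-04-25T08:51:31.273Z")
        d = rec.to_dict()
        assert d["activityName"] == "flushingToilet"
        assert d["audioChannel"] == "audioData"
        assert d["3DDirection"] == [0.61, 0.49, 0.60]
        assert d["timestamp"] == "2019-04-25T08:51:31.273Z"

    def test_jsonl_roundtrip(self, tmp_path):
        path = tmp_path / "store.jsonl"
        store = sa.AnnotationStore(path)
        rec = sa.make_record("flushingToilet", "audioData",
                             [0.61, 0.49, 0.60], "BATH",
                             "2019-04-25T08:51:31.273Z")
        store.append(rec)
        back = sa.AnnotationStore.read(path)
        assert len(back) == 1
        assert back[0] == rec

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sa.make_record("", "audioData", [0, 0, 0], "ANY",
                           "2019-01-01T00:00:00Z")

    def test_missing_field_rejected(self):
        with pytest.raises(ValueError, match="missing field"):
            sa.AnnotationRecord.from_dict({"activityName": "x"})

    def test_unparseable_timestamp_rejected(self):
        with pytest.raises(ValueError):
            sa.make_record("x", "audioData", [0, 0, 0], "ANY", "yesterday")


class TestSerialization:
    def test_sound_class_roundtrip(self, trained_pair, rng):
        _, (cls_a, _) = trained_pair
        back = sa.SoundClass.from_dict(json.loads(json.dumps(cls_a.to_dict())))
        x = rng.normal(size=(50, 13))
        assert back.hmm.score(x) == pytest.approx(cls_a.hmm.score(x), rel=1e-9)
        np.testing.assert_allclose(back.centroid, cls_a.centroid)


@pytest.fixture(scope="module")
def tiny_world(small_audio_training):
    train = small_audio_training
    names = ["runningWaterSink", "runningWaterShower", "blenderWorking"]
    feats = {n: [af.mfcc(c) for c in train.clips[n]] for n in names}
    models = [sa.train_class(n, feats[n], train.directions[n],
                             mobile=train.class_defs[n].mobile, seed=0,
                             semantic_position=train.class_defs[n].semantic_position)
              for n in names]
    cfg = sa.calibrate_thresholds(models, feats)
    return train, models, cfg


class TestPipeline:
    def _events(self, train, names, seed=11):
        spec = fx.AudioFixtureSpec(samples_per_class=4, seed=seed)
        rng = np.random.default_rng(seed)
        events, truths = [], []
        for n in names:
            cdef = train.class_defs[n]
            x = fx._synth_clip(cdef, 3.0, 16_000, spec.target_rms, rng)
            d = fx._sample_direction(cdef, spec.direction_spread, rng)
            events.append(af.SoundEvent(
                clip=af.AudioClip(x, 16_000), direction=d, start_s=0.0,
                end_s=3.0, energy_trace=np.array([0.7])))
            truths.append(n)
        return events, truths

    def test_sound_only_equals_all_mobile(self, tiny_world):
        """Disabling direction is the same as making every class mobile."""
        train, models, cfg = tiny_world
        events, truths = self._events(
            train, ["runningWaterSink", "blenderWorking"] * 2)
        _, conf_a, acc_a = sa.run_pipeline(events, truths, models, cfg,
                                           use_direction=False)
        mobiled = [sa.SoundClass(m.name, m.hmm, np.zeros(3), 10_000,
                                 m.n_training, True, m.semantic_position)
                   for m in models]
        _, conf_b, acc_b = sa.run_pipeline(events, truths, mobiled, cfg,
                                           use_direction=True)
        assert acc_a == acc_b
        assert conf_a.to_numpy().tolist() == conf_b.to_numpy().tolist()

    def test_all_unknown_stream_never_autolabels(self, tiny_world, rng):
        train, models, cfg = tiny_world
        events = []
        for ud in fx.UNKNOWN_CLASSES:
            x = fx._synth_clip(ud, 3.0, 16_000, 0.25, rng)
            events.append(af.SoundEvent(
                clip=af.AudioClip(x, 16_000), direction=rng.normal(size=3),
                start_s=0.0, end_s=3.0, energy_trace=np.array([0.7])))
        annotator = sa.Annotator(models, cfg)
        for ev in events:
            decision, _, _ = annotator.process_event(
                ev, responder=lambda d: "unknownThing")
            assert decision.action != sa.Action.AUTO_LABEL

    def test_direction_fixes_confusable_pair(self, tiny_world):
        """Sink and shower share a spectral envelope; with direction the
        wrong auto-labels become corrected queries."""
        train, models, cfg = tiny_world
        events, truths = self._events(
            train, ["runningWaterSink", "runningWaterShower"] * 3)
        _, _, acc_sound = sa.run_pipeline(events, truths, models, cfg,
                                          use_direction=False)
        _, _, acc_dir = sa.run_pipeline(events, truths, models, cfg,
                                        use_direction=True)
        assert acc_dir >= acc_sound
        assert acc_dir >= 0.9

    def test_store_size_equals_labeled_events(self, tiny_world):
        train, models, cfg = tiny_world
        events, truths = self._events(
            train, ["runningWaterSink", "blenderWorking"])
        store = sa.AnnotationStore()
        records, conf, _ = sa.run_pipeline(events, truths, models, cfg,
                                           use_direction=True, store=store)
        assert len(records) == len(store)
        assert conf.to_numpy().sum() == len(events)

    def test_label_renaming_equivariance(self, tiny_world, rng):
        """Renaming every class renames outputs without changing scores."""
        train, models, cfg = tiny_world
        x = rng.normal(size=(60, 13))
        renamed = [sa.SoundClass("X" + m.name, m.hmm, m.centroid,
                                 m.centroid_threshold, m.n_training,
                                 m.mobile, m.semantic_position)
                   for m in models]
        best1, s1 = sa.score(models, x)
        best2, s2 = sa.score(renamed, x)
        assert best2 == "X" + best1
        for name, v in s1.items():
            assert s2["X" + name] == pytest.approx(v, abs=1e-12)
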