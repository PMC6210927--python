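"""Hierarchical classifier: training, stream classification, segmentation, CV."""

import numpy as np
import pytest

import tugsense as ts
from tugsense.model import (
    LEVEL_ALPHABET,
    ClassifierConfig,
    LabelSegment,
    classify_stream,
    load_model,
    save_model,
    segment_labels,
    segments_to_track,
    train_classifier,
)
from tugsense.features import FeatureSpec, WindowSpec
from tugsense.recording import FilterSpec, ImuRecording


def _config(method="boosted_decision_trees", level="static", **hp):
    return ClassifierConfig(
        level=level,
        method=method,
        window=WindowSpec(1.0, 0.5),
        filter=FilterSpec("none"),
        features=(FeatureSpec("mean", "acc"),),
        hyperparams=hp,
    )


def _clusters(rng, n=300):
    X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(6, 1, (n, 4))])
    y = np.array(["sit"] * n + ["stand"] * n, dtype=object)
    idx = rng.permutation(2 * n)
    return X[idx], y[idx]


class TestTraining:
    @pytest.mark.parametrize(
        "method,hp",
        [
            ("boosted_decision_trees", {"rounds": 50}),
            ("boosted_decision_stump", {"rounds": 50}),
            ("multilayer_perceptron", {"hidden_layers": 2, "hidden_nodes": 8, "max_iter": 300}),
        ],
    )
    def test_separable_clusters_are_learned(self, rng, method, hp):
        X, y = _clusters(rng)
        clf = train_classifier(X, y, _config(method, **hp), seed=0)
        assert np.mean(clf.predict(X) == y) >= 0.99

    def test_single_class_error_names_missing_classes(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.array(["sit"] * 50, dtype=object)
        with pytest.raises(ValueError, match="stand"):
            train_classifier(X, y, _config(), seed=0)

    def test_alien_labels_rejected(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.array(["walk"] * 25 + ["sit"] * 25, dtype=object)
        with pytest.raises(ValueError, match="alphabet"):
            train_classifier(X, y, _config(level="static"), seed=0)

    def test_save_load_round_trip_predictions(self, rng, tmp_path, trained_model):
        path = tmp_path / "bundle.joblib"
        save_model(trained_model, path)
        back = load_model(path)
        rec = ts.generate(
            ts.ActivityScript(ts.standard_tug_script(), seed=5), 100.0
        )
        np.testing.assert_array_equal(classify_stream(rec, back), classify_stream(rec, trained_model))

    def test_shuffled_labels_score_at_chance(self, rng):
        """With labels randomly permuted, cross-validated accuracy must sit
        within 3 standard errors of the 50% chance level."""
        X, y = _clusters(rng, n=250)
        y = rng.permutation(y)
        accs = []
        folds = np.array_split(np.arange(len(y)), 5)
        for f in folds:
            mask = np.zeros(len(y), dtype=bool)
            mask[f] = True
            clf = train_classifier(X[~mask], y[~mask], _config(rounds=50), seed=0)
            accs.append(np.mean(clf.predict(X[mask]) == y[mask]))
        acc = np.mean(accs)
        se = np.sqrt(0.25 / len(y))
        assert abs(acc - 0.5) <= 3 * se


class TestSegmentation:
    def test_run_length_encoding(self):
        track = ["sit"] * 100 + ["walk"] * 300 + ["sit"] * 100
        segs = segment_labels(track, 100.0)
        assert [(s.label, s.duration_s) for s in segs] == [
            ("sit", 1.0), ("walk", 3.0), ("sit", 1.0)
        ]

    def test_short_blip_absorbed(self):
        track = ["sit"] * 200 + ["walk"] * 3 + ["sit"] * 200
        segs = segment_labels(track, 100.0, min_duration_s=0.2)
        assert len(segs) == 1
        assert segs[0].label == "sit"
        assert segs[0].duration_s == pytest.approx(4.03)

    def test_segmentation_is_idempotent(self, rng):
        track = rng.choice(["sit", "walk", "turn"], size=500)
        segs = segment_labels(track, 100.0, min_duration_s=0.1)
        rendered = segments_to_track(segs, 100.0)
        again = segment_labels(rendered, 100.0, min_duration_s=0.1)
        assert [(s.label, s.start_s, s.end_s) for s in segs] == [
            (s.label, s.start_s, s.end_s) for s in again
        ]

    def test_output_alternates_labels(self, rng):
        track = rng.choice(["a", "b"], size=300)
        segs = segment_labels(track, 100.0, min_duration_s=0.15)
        assert all(s1.label != s2.label for s1, s2 in zip(segs, segs[1:]))

    def test_segment_requires_positive_duration(self):
        with pytest.raises(ValueError):
            LabelSegment("sit", 2.0, 2.0)


class TestStreamClassification:
    def test_pure_walking_stream(self, trained_model):
        rec = ts.generate(ts.ActivityScript((("walk", 10.0),), seed=3), 100.0)
        pred = classify_stream(rec, trained_model)
        covered = pred != "unknown"
        assert np.mean(pred[covered] == "walk") >= 0.9

    def test_zero_signal_is_a_static_posture(self, trained_model):
        n = 1500
        rec = ImuRecording(np.arange(n) / 100, np.zeros((n, 3)), np.zeros((n, 3)), 100.0)
        pred = classify_stream(rec, trained_model)
        covered = pred[pred != "unknown"]
        assert covered.size > 0
        assert set(covered) <= {"sit", "stand"}

    def test_labels_come_from_the_fine_alphabet(self, trained_model):
        rec = ts.generate(ts.ActivityScript(ts.standard_tug_script(), seed=9), 100.0)
        pred = classify_stream(rec, trained_model)
        fine = set(LEVEL_ALPHABET["static"] + LEVEL_ALPHABET["dynamic"] + LEVEL_ALPHABET["transition"])
        assert set(pred) <= fine | {"unknown"}

    def test_short_recording_is_all_unknown(self, trained_model):
        n = 60
        rec = ImuRecording(np.arange(n) / 100, np.zeros((n, 3)), np.zeros((n, 3)), 100.0)
        with pytest.warns(UserWarning):
            pred = classify_stream(rec, trained_model)
        assert set(pred) == {"unknown"}

    def test_concatenation_invariance_away_from_junction(self, trained_model):
        walk = ts.generate(ts.ActivityScript((("walk", 8.0),), seed=21), 100.0)
        sit = ts.generate(ts.ActivityScript((("sit", 8.0),), seed=22), 100.0)
        n1, n2 = len(walk), len(sit)
        joined = ImuRecording(
            np.arange(n1 + n2) / 100.0,
            np.vstack([walk.acc, sit.acc]),
            np.vstack([walk.gyro, sit.gyro]),
            100.0,
        )
        pred_joined = classify_stream(joined, trained_model)
        pred_walk = classify_stream(walk, trained_model)
        pred_sit = classify_stream(sit, trained_model)
        margin = 300  # one largest-window length (3 s) from junction and edges
        a = slice(margin, n1 - margin)
        b = slice(n1 + margin, n1 + n2 - margin)
        assert np.mean(pred_joined[a] == pred_walk[a]) >= 0.98
        assert np.mean(pred_joined[b] == pred_sit[margin : n2 - margin]) >= 0.98

    def test_walk_boundaries_recovered_within_half_second(self, trained_model):
        """Boundary times of true walking segments are recovered within 0.5 s
        for at least 90% of segments."""
        corpus = ts.generate_corpus(6, seed=77)
        total, good = 0, 0
        for rec, man in zip(corpus.recordings, corpus.manifest):
            pred = classify_stream(rec, trained_model)
            segs = segment_labels(pred, rec.sample_rate, min_duration_s=0.5)
            pred_walks = [s for s in segs if s.label == "walk"]
            for truth in man["segments"]:
                if truth["label"] != "walk":
                    continue
                total += 1
                for s in pred_walks:
                    if (
                        abs(s.start_s - truth["start_s"]) <= 0.5
                        and abs(s.end_s - truth["end_s"]) <= 0.5
                    ):
                        good += 1
                        break
        assert total >= 10
        assert good / total >= 0.9


class TestCrossValidation:
    def test_pooled_metrics_and_fold_balance(self, train_corpus):
        configs = ts.default_configs()
        report = ts.cross_validate(train_corpus.recordings, configs, n_folds=5, seed=1)
        walk = report["dynamic"]["walk"]
        # definitional identities on the pooled counts
        total = walk.tp + walk.fp + walk.fn + walk.tn
        assert walk.accuracy == pytest.approx((walk.tp + walk.tn) / total)
        assert walk.f1 <= max(walk.precision, walk.recall) + 1e-12
        assert walk.f1 >= 0.9
        # every subject's windows appear exactly once as validation
        n_subjects = len({r.subject_id for r in train_corpus.recordings})
        sizes = [len(f) for f in np.array_split(np.arange(n_subjects), 5)]
        assert max(sizes) - min(sizes) <= 1
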