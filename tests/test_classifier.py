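"""Threshold training set, remapping, the network, and circular error."""

import numpy as np
import pandas as pd
import pytest

import daytunes as dt
from daytunes.classifier import (
    CLASSIFIER_FEATURES,
    THRESHOLD_FEATURES,
    ClassifierSpec,
    PlaylistPrediction,
    SubdivisionNetwork,
    agreement_report,
    build_training_set,
    circular_error,
    class_weights,
    classify_playlist,
    remap_features,
    train_classifier,
)
from daytunes.subdivisions import ClusterSummary, SubdivisionModel
from daytunes.synthetic import SUBDIVISIONS


def toy_model():
    """Hand-built 5-subdivision model over the four threshold features.

    Directions vs the grand mean (0.5 everywhere), written +/-:
    morning (+,+,+,+) at (.7,.7,.6,.6) sd .5; afternoon all - at .3;
    evening (+,-,+,-); night (-,+,-,+); late-night all + at .9 sd .05.
    """
    spec = {
        "morning": ((0.7, 0.7, 0.6, 0.6), 0.5, 6),
        "afternoon": ((0.3, 0.3, 0.3, 0.3), 0.1, 12),
        "evening": ((0.7, 0.3, 0.6, 0.3), 0.1, 20),
        "night": ((0.3, 0.7, 0.3, 0.7), 0.1, 23),
        "late_night": ((0.9, 0.9, 0.9, 0.9), 0.05, 4),
    }
    clusters = []
    for name, (means, sd, onset) in spec.items():
        centroid = pd.Series(dict(zip(THRESHOLD_FEATURES, means)))
        clusters.append(
            ClusterSummary(
                name=name,
                mode_onset=onset,
                onset_sd=0.0,
                mode_offset=(onset + 5) % 24,
                n_hours=33,
                centroid_normalized=centroid * 0.0,
                centroid_raw=centroid,
                centroid_raw_sd=pd.Series(dict.fromkeys(THRESHOLD_FEATURES, sd)),
                relative_profile=centroid - 0.5,
            )
        )
    labels = pd.Series(
        np.ones(168, dtype=int), index=pd.RangeIndex(1, 169, name="hour_of_week")
    )
    return SubdivisionModel(
        k=5,
        labels=labels,
        clusters=clusters,
        cyclic_order_ok=True,
        grand_mean=pd.Series(dict.fromkeys(THRESHOLD_FEATURES, 0.5)),
    )


def toy_tracks(values):
    rows = []
    for i, v in enumerate(values):
        row = dict(zip(THRESHOLD_FEATURES, v))
        row["track_id"] = f"t{i}"
        rows.append(row)
    return pd.DataFrame(rows)


class TestBuildTrainingSet:
    def test_hand_derived_assignments(self):
        catalog = toy_tracks(
            [
                # morning (dist 0.6) + late_night (dist 1.0) -> morning
                (0.95, 0.95, 0.95, 0.95),
                (0.8, 0.8, 0.8, 0.8),  # morning only
                (0.2, 0.2, 0.2, 0.2),  # afternoon only
                (0.8, 0.2, 0.7, 0.2),  # evening only
                (0.2, 0.8, 0.2, 0.8),  # night only
                (0.3, 0.3, 0.3, 0.3),  # exactly at afternoon means: nothing
                (0.95, 0.85, 0.95, 0.95),  # morning (late-night energy fails)
                (0.25, 0.2, 0.28, 0.1),  # afternoon only
                # morning (dist 0.54) + late_night (dist 0.4) -> late_night
                (0.92, 0.92, 0.92, 0.92),
            ]
        )
        out = build_training_set(catalog, toy_model())
        got = dict(zip(out["track_id"], out["label"]))
        assert got == {
            "t0": "morning",
            "t1": "morning",
            "t2": "afternoon",
            "t3": "evening",
            "t4": "night",
            "t6": "morning",
            "t7": "afternoon",
            "t8": "late_night",
        }

    def test_track_exactly_at_means_does_not_qualify(self):
        catalog = toy_tracks([(0.3, 0.3, 0.3, 0.3)] * 2 + [(0.95,) * 4])
        with pytest.raises(ValueError, match="no qualifying tracks"):
            build_training_set(catalog, toy_model())

    def test_fitted_model_trainset_covers_classes_above_chance(self, small_run):
        # regimes overlap broadly at the default separation, so threshold
        # selection is enriched for, not pure in, the true regime
        trainset = build_training_set(small_run["catalog"], small_run["model"])
        assert set(trainset["label"]) == set(SUBDIVISIONS)
        purity = (trainset["label"] == trainset["true_regime"]).mean()
        assert purity > 1 / 3  # chance level is 1/5


class TestRemap:
    @pytest.mark.parametrize(
        "feature,value,expected",
        [
            ("loudness", -60.0, -1.0),
            ("loudness", 12.0, 1.0),
            ("loudness", -24.0, 0.0),
            ("loudness", -99.0, -1.0),  # clamped
            ("tempo", 130.0, 0.0),
            ("tempo", 40.0, -1.0),
            ("tempo", 220.0, 1.0),
            ("tempo", 500.0, 1.0),  # clamped
            ("danceability", 0.75, 0.5),
            ("valence", 0.0, -1.0),
            ("energy", 1.0, 1.0),
        ],
    )
    def test_known_mappings(self, feature, value, expected):
        base = {
            "danceability": 0.5,
            "energy": 0.5,
            "loudness": -24.0,
            "liveness": 0.5,
            "valence": 0.5,
            "tempo": 130.0,
        }
        base[feature] = value
        out = remap_features(base)
        idx = CLASSIFIER_FEATURES.index(feature)
        assert out[idx] == pytest.approx(expected)

    def test_monotone_per_feature(self, rng):
        frame = pd.DataFrame(
            {
                "danceability": np.sort(rng.random(50)),
                "energy": np.sort(rng.random(50)),
                "loudness": np.sort(rng.uniform(-80, 20, 50)),
                "liveness": np.sort(rng.random(50)),
                "valence": np.sort(rng.random(50)),
                "tempo": np.sort(rng.uniform(20, 260, 50)),
            }
        )
        out = remap_features(frame)
        assert (np.diff(out, axis=0) >= 0).all()
        assert (out > -1.0 - 1e-12).all() and (out < 1.0 + 1e-12).all()


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        w = class_weights({c: 10 for c in SUBDIVISIONS})
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_hand_computed_unbalanced(self):
        w = class_weights({"a": 10, "b": 10, "c": 10, "d": 10, "e": 60})
        assert w["a"] == pytest.approx(2.0)
        assert w["e"] == pytest.approx(1 / 3)

    def test_count_weighted_mean_is_one(self):
        counts = {"a": 3, "b": 17, "c": 80}
        w = class_weights(counts)
        total = sum(counts.values())
        assert sum(w[c] * n for c, n in counts.items()) / total == pytest.approx(1.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights({"a": 0, "b": 5})


def mini_trainset(n_per_class=60, seed=0):
    """Small near-separable labelled set over the six network features."""
    rng = np.random.default_rng(seed)
    centers = {
        "morning": (0.8, 0.8, -5.0, 0.2, 0.8, 100.0),
        "afternoon": (0.2, 0.5, -10.0, 0.5, 0.5, 160.0),
        "evening": (0.9, 0.3, -15.0, 0.8, 0.2, 200.0),
        "night": (0.3, 0.2, -30.0, 0.3, 0.3, 60.0),
        "late_night": (0.6, 0.9, -45.0, 0.6, 0.9, 130.0),
    }
    rows = []
    for label, center in centers.items():
        for _ in range(n_per_class):
            vals = np.array(center) + rng.normal(0, 0.02, 6) * np.array(
                [1, 1, 30, 1, 1, 300]
            ) * 0.1
            row = dict(zip(CLASSIFIER_FEATURES, vals))
            row["label"] = label
            rows.append(row)
    return pd.DataFrame(rows)


class TestNetwork:
    def test_probability_rows_sum_to_one(self):
        net = SubdivisionNetwork(list(SUBDIVISIONS), ClassifierSpec(), seed=0)
        X = np.random.default_rng(0).uniform(-1, 1, size=(17, 6))
        probs = net.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_training_identical(self):
        ts = mini_trainset()
        spec = ClassifierSpec(max_epochs=3, patience=3)
        _, m1 = train_classifier(ts, spec, seed=5)
        _, m2 = train_classifier(ts, spec, seed=5)
        assert m1 == m2

    def test_json_round_trip_preserves_predictions(self):
        net = SubdivisionNetwork(list(SUBDIVISIONS), ClassifierSpec(), seed=1)
        restored = SubdivisionNetwork.from_json(net.to_json())
        X = np.random.default_rng(1).uniform(-1, 1, size=(5, 6))
        assert np.allclose(net.predict_proba(X), restored.predict_proba(X))

    def test_learns_separable_classes(self):
        # a faster learning rate keeps this unit check cheap; convergence
        # under the canonical rate is exercised end-to-end elsewhere
        ts = mini_trainset(n_per_class=150, seed=1)
        spec = ClassifierSpec(learning_rate=5e-3, max_epochs=80, patience=80)
        _, metrics = train_classifier(ts, spec, seed=0)
        assert metrics["holdout_accuracy"] > 0.9


class TestPlaylist:
    def test_single_track_playlist_equals_track_argmax(self):
        net = SubdivisionNetwork(list(SUBDIVISIONS), ClassifierSpec(), seed=2)
        tracks = mini_trainset(n_per_class=1, seed=3).head(1)
        pred = classify_playlist(net, tracks)
        track_probs = net.predict_proba(tracks[list(CLASSIFIER_FEATURES)])
        assert pred.predicted == SUBDIVISIONS[int(track_probs[0].argmax())]

    def test_tie_breaks_to_earlier_subdivision(self):
        probs = np.array([[1.0, 0, 0, 0, 0], [0, 1.0, 0, 0, 0]])
        pred = PlaylistPrediction(
            classes=tuple(SUBDIVISIONS),
            track_probabilities=probs,
            mean_probabilities=probs.mean(axis=0),
        )
        assert pred.predicted == "morning"

    def test_mean_probabilities_are_track_average(self):
        net = SubdivisionNetwork(list(SUBDIVISIONS), ClassifierSpec(), seed=4)
        tracks = mini_trainset(n_per_class=2, seed=5)
        pred = classify_playlist(net, tracks)
        manual = net.predict_proba(tracks[list(CLASSIFIER_FEATURES)]).mean(axis=0)
        assert np.allclose(pred.mean_probabilities, manual)

    def test_empty_playlist_rejected(self):
        net = SubdivisionNetwork(list(SUBDIVISIONS), ClassifierSpec(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            classify_playlist(net, mini_trainset().head(0))


class TestCircularError:
    def test_identity(self):
        for c in range(1, 6):
            assert circular_error(c, c) == 0

    @pytest.mark.parametrize("res,pred,expected", [(1, 5, 1), (2, 5, 2), (1, 3, 2), (4, 5, 1)])
    def test_ring_distances(self, res, pred, expected):
        assert circular_error(res, pred) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            circular_error(0, 3)
        with pytest.raises(ValueError):
            circular_error(1, 6)


class TestAgreementReport:
    def test_perfect_agreement(self):
        report = agreement_report([(c, c) for c in range(1, 6)])
        assert report.loc["overall", "agreement_pct"] == 100.0
        assert report.loc["overall", "mean_error"] == 0.0

    def test_uniform_responses_mean_error(self):
        report = agreement_report([(3, r) for r in range(1, 6)])
        assert report.loc["overall", "mean_error"] == pytest.approx(1.2)

    def test_toy_report_hand_computed(self):
        pairs = [(1, 1), (1, 2), (1, 4), (2, 2), (2, 5), (3, 3), (3, 3), (3, 1), (4, 4), (5, 2)]
        report = agreement_report(pairs)
        # pred 1: errors 0,1,2 -> 1/3 agree, mean 1.0
        assert report.loc["morning", "agreement_pct"] == pytest.approx(100 / 3)
        assert report.loc["morning", "mean_error"] == pytest.approx(1.0)
        # pred 3: errors 0,0,2 -> 2/3 agree
        assert report.loc["evening", "agreement_pct"] == pytest.approx(200 / 3)
        assert report.loc["overall", "n"] == 10

    def test_empty_input(self):
        assert agreement_report([]).empty
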