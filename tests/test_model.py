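"""Feature engineering and the boosted severity model."""

import math

import numpy as np
import pandas as pd
import pytest

from msdss.cohort import SchemaError, TreatmentEpoch, ValidationError
from msdss.model import (
    FEATURE_NAMES,
    build_features,
    evaluate,
    features_frame,
    load_model,
    predict_msdss,
    reduce_and_retrain,
    relative_influence,
    save_model,
    train,
)

from conftest import make_patient

FAST = {"shrinkage": 0.05, "tree_grid": (150,), "cv_folds": 3}


def noise_frame(n, n_features=5, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"f{i}" for i in range(n_features)]
    return pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)


class TestBuildFeatures:
    def test_never_treated_degenerate_case(self):
        p = make_patient("P1", [45.0, 46.0])
        f = build_features(p)
        assert math.isnan(f["onset_to_first_therapy_years"])
        assert f["therapy_type"] == 0.0
        assert f["adj_minus_measured_cw"] == 0.0
        assert f["n_short_dmts"] == 0.0
        assert f["cumulative_efficacy_followup"] == 0.0

    def test_onset_to_first_therapy_is_a_difference(self):
        p = make_patient(
            "P1", [45.0, 46.0], onset_age=30.0, treatments=[TreatmentEpoch(33.0, 36.0, "low")]
        )
        assert build_features(p)["onset_to_first_therapy_years"] == pytest.approx(3.0)

    def test_short_dmt_rule_and_therapy_type(self):
        p = make_patient(
            "P1",
            [45.0, 46.0],
            treatments=[TreatmentEpoch(40.0, 40.3, "low"), TreatmentEpoch(41.0, 43.0, "high")],
        )
        f = build_features(p)
        assert f["n_short_dmts"] == 1.0
        assert f["therapy_type"] == 3.0  # both classes received

    def test_unknown_class_epochs_do_not_change_therapy_type(self):
        p = make_patient(
            "P1", [45.0, 46.0], treatments=[TreatmentEpoch(40.0, 42.0, "none_or_unknown")]
        )
        assert build_features(p)["therapy_type"] == 0.0

    def test_adjustment_never_below_measurement(self, seed1_cohort):
        patients, _ = seed1_cohort
        feats = features_frame(patients)
        assert list(feats.columns) == FEATURE_NAMES
        assert (feats["adj_minus_measured_cw"] >= -1e-12).all()

    def test_anchor_last_visit_uses_later_age(self):
        p = make_patient("P1", [45.0, 48.0])
        assert build_features(p, anchor="last_visit")["age"] == 48.0
        assert build_features(p, anchor="first_visit")["age"] == 45.0

    def test_no_usable_visit_rejected(self):
        with pytest.raises(ValidationError):
            build_features(make_patient("P1", []))


class TestTrain:
    def test_constant_target_predicts_the_constant(self):
        X = noise_frame(30)
        m = train(X, np.full(30, 2.5), FAST, seed=0)
        assert np.all(predict_msdss(m, X) == 2.5)
        assert (relative_influence(m) == 0).all()

    def test_planted_signal_feature_dominates(self):
        X = noise_frame(500, n_features=6, seed=1)
        y = X["f2"].to_numpy()
        m = train(X, y, FAST, seed=1)
        assert relative_influence(m)["f2"] > 50

    def test_same_seed_is_deterministic(self):
        X = noise_frame(100, seed=3)
        y = X["f0"] + np.random.default_rng(4).normal(0, 0.5, 100)
        a = train(X, y, {**FAST, "tree_grid": (100, 200)}, seed=7)
        b = train(X, y, {**FAST, "tree_grid": (100, 200)}, seed=7)
        assert a.n_trees == b.n_trees
        assert np.array_equal(predict_msdss(a, X), predict_msdss(b, X))

    def test_non_finite_target_rejected(self):
        X = noise_frame(20)
        with pytest.raises(ValidationError):
            train(X, np.r_[np.ones(19), np.nan], FAST)


class TestRelativeInfluence:
    def test_sums_to_one_hundred(self):
        X = noise_frame(80, seed=2)
        y = X["f0"] + 0.5 * X["f1"]
        m = train(X, y, FAST, seed=2)
        assert relative_influence(m).sum() == pytest.approx(100.0, abs=1e-6)
        assert (relative_influence(m) >= 0).all()

    def test_single_feature_model_gets_everything(self):
        X = noise_frame(60, n_features=1, seed=5)
        y = X["f0"].to_numpy()
        m = train(X, y, FAST, seed=5)
        assert relative_influence(m)["f0"] == pytest.approx(100.0)

    def test_noise_features_stay_near_uniform_share(self):
        # no feature should grab influence far beyond 1/p on pure noise
        maxima = []
        for seed in range(20):
            X = noise_frame(120, n_features=8, seed=seed)
            y = np.random.default_rng(1000 + seed).normal(size=120)
            m = train(X, y, FAST, seed=seed)
            maxima.append(relative_influence(m).max())
        assert np.median(maxima) < 3 * 100.0 / 8

    def test_untrained_model_rejected(self):
        X = noise_frame(30)
        m = train(X, X["f0"].to_numpy(), FAST, seed=0)
        m.estimator = None
        m.constant_prediction = None
        with pytest.raises(ValidationError):
            relative_influence(m)


class TestReduceAndRetrain:
    def test_keeps_exactly_the_features_above_threshold(self):
        X = noise_frame(300, n_features=6, seed=4)
        y = 2 * X["f1"] + X["f4"] + 0.1 * np.random.default_rng(4).normal(size=300)
        m = train(X, y, FAST, seed=4)
        infl = relative_influence(m)
        red = reduce_and_retrain(m, X, y, threshold=4.0)
        assert red.feature_names == [f for f in m.feature_names if infl[f] > 4.0]
        assert red.reduced

    def test_zero_threshold_keeps_all_features(self):
        X = noise_frame(100, seed=6)
        y = X["f0"] + X["f1"]
        m = train(X, y, FAST, seed=6)
        red = reduce_and_retrain(m, X, y, threshold=0.0)
        assert red.feature_names == m.feature_names

    def test_impossible_threshold_rejected(self):
        X = noise_frame(100, seed=6)
        y = X["f0"]
        m = train(X, y, FAST, seed=6)
        with pytest.raises(ValidationError, match="threshold"):
            reduce_and_retrain(m, X, y, threshold=1000.0)


class TestPredict:
    def test_monotone_single_feature_response(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"x": rng.uniform(0, 10, 400)})
        y = X["x"].to_numpy()
        m = train(X, y, FAST, seed=8)
        grid = pd.DataFrame({"x": np.linspace(0.5, 9.5, 50)})
        preds = predict_msdss(m, grid)
        assert np.all(np.diff(preds) >= -1e-9)

    def test_missing_comris_is_tolerated(self, seed1_cohort):
        patients, _ = seed1_cohort
        feats = features_frame(patients[:150])
        y = np.arange(150, dtype=float)
        m = train(feats, y, FAST, seed=0)
        one = feats.iloc[0].copy()
        one["comris_ctd"] = math.nan
        assert np.isfinite(predict_msdss(m, one))

    def test_unknown_feature_rejected(self):
        X = noise_frame(50)
        m = train(X, X["f0"].to_numpy(), FAST, seed=0)
        with pytest.raises(SchemaError):
            predict_msdss(m, pd.DataFrame({"wrong": [1.0]}))


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 200)})
        y = X["x"].to_numpy()
        m = train(X, y, {"shrinkage": 0.3, "tree_grid": (400,), "cv_folds": 3}, seed=9)
        ev = evaluate(m, X, y)
        assert ev.r > 0.99 and ev.n == 200

    def test_independent_target_scores_near_zero(self):
        X = noise_frame(1000, seed=10)
        y_train = X["f0"].to_numpy()
        m = train(X, y_train, FAST, seed=10)
        y_indep = np.random.default_rng(99).normal(size=1000)
        ev = evaluate(m, X, y_indep)
        assert abs(ev.r) < 0.1

    def test_zero_variance_rejected(self):
        X = noise_frame(30)
        m = train(X, np.full(30, 1.0), FAST, seed=0)
        with pytest.raises(ValidationError):
            evaluate(m, X, np.arange(30, dtype=float))


class TestPersistence:
    def test_round_trip_with_metadata_sidecar(self, tmp_path, seed1_cohort):
        patients, _ = seed1_cohort
        feats = features_frame(patients[:100])
        y = np.linspace(-1, 2, 100)
        m = train(feats, y, FAST, seed=2)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        back = load_model(path)
        assert np.array_equal(predict_msdss(back, feats), predict_msdss(m, feats))
        meta = path.with_suffix(".json").read_text()
        assert "indicator_plus_median" in meta and "relative_influence" in meta
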