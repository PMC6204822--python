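"""Classifier: kappa, balancing, training, prediction, audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sealteb import classifier as clf
from sealteb.types import BEHAVIOURS


def brute_force_kappa(true_labels, pred_labels):
    """Kappa straight from label pairs: observed vs chance agreement."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    n = len(true_labels)
    classes = sorted(set(true_labels) | set(pred_labels))
    p_o = sum(t == p for t, p in zip(true_labels, pred_labels)) / n
    p_e = sum(
        (true_labels.count(c) / n) * (pred_labels.count(c) / n) for c in classes
    )
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert clf.cohens_kappa(np.diag([10, 10, 10, 10])) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        assert clf.cohens_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_evaluated_two_class_case(self):
        assert clf.cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.40)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            clf.cohens_kappa(np.zeros((3, 3)))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            clf.cohens_kappa(np.ones((2, 3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_on_random_label_pairs(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        n = int(rng.integers(10, 200))
        true = rng.integers(0, k, n)
        pred = np.where(rng.random(n) < 0.6, true, rng.integers(0, k, n))
        confusion = np.zeros((k, k), dtype=int)
        for t, p in zip(true, pred):
            confusion[t, p] += 1
        assert clf.cohens_kappa(confusion) == pytest.approx(
            brute_force_kappa(true, pred), abs=1e-12
        )


def _labelled_frame(counts, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in counts.items():
        for _ in range(n):
            rows.append({"label": label, "v": rng.normal()})
    return pd.DataFrame(rows)


class TestDownsampleBalanced:
    def test_equal_counts_after_downsampling(self):
        df = _labelled_frame(
            {"foraging": 100, "travelling": 80, "grooming": 50, "resting": 50}
        )
        out = clf.downsample_balanced(df, 50, seed=0)
        assert len(out) == 200
        assert set(out["label"].value_counts()) == {50}

    def test_n_clamped_to_rarest_class_with_warning(self, caplog):
        df = _labelled_frame({"foraging": 100, "resting": 50})
        with caplog.at_level("WARNING", logger="sealteb.classifier"):
            out = clf.downsample_balanced(df, 60, seed=0)
        assert set(out["label"].value_counts()) == {50}
        assert any("lowering" in r.message for r in caplog.records)

    def test_same_seed_same_selection(self):
        df = _labelled_frame({"foraging": 100, "resting": 100})
        a = clf.downsample_balanced(df, 30, seed=7)
        b = clf.downsample_balanced(df, 30, seed=7)
        assert list(a.index) == list(b.index)

    def test_empty_class_named_in_error(self):
        df = _labelled_frame({"foraging": 10, "resting": 10})
        with pytest.raises(ValueError, match="grooming"):
            clf.downsample_balanced(df, 5, seed=0, classes=BEHAVIOURS)


class TestTrainGBM:
    def test_separable_synthetic_data_recovered(self, trained_model):
        _, report = trained_model
        assert report.out_of_sample_accuracy >= 0.80
        assert report.kappa >= 0.70

    def test_confusion_rows_sum_to_class_test_counts(self, trained_model):
        _, report = trained_model
        assert (report.confusion.to_numpy().sum(axis=1) > 0).all()
        assert report.confusion.to_numpy().sum() > 0
        assert -1 <= report.kappa <= 1
        assert 0 <= report.out_of_sample_accuracy <= 1

    def test_shuffled_labels_give_chance_kappa(self, captive_features):
        df = captive_features.copy()
        rng = np.random.default_rng(0)
        df["label"] = rng.permutation(df["label"].to_numpy())
        cfg = clf.TrainConfig(
            parameter_grid={"max_depth": (3,), "learning_rate": (0.3,),
                            "n_estimators": (30,), "subsample": (1.0,)},
            cv_folds=3, seed=0,
        )
        _, report = clf.train_gbm(df, cfg)
        assert abs(report.kappa) <= 0.1

    def test_training_is_deterministic(self, captive_features):
        cfg = clf.TrainConfig(
            parameter_grid={"max_depth": (3, 5), "learning_rate": (0.3,),
                            "n_estimators": (30,), "subsample": (1.0,)},
            cv_folds=3, seed=5,
        )
        _, r1 = clf.train_gbm(captive_features, cfg)
        _, r2 = clf.train_gbm(captive_features, cfg)
        assert r1.cross_validation_accuracy == r2.cross_validation_accuracy
        assert r1.out_of_sample_accuracy == r2.out_of_sample_accuracy
        assert r1.kappa == r2.kappa
        assert r1.chosen_hyperparameters == r2.chosen_hyperparameters
        assert r1.confusion.equals(r2.confusion)

    def test_non_finite_feature_rejected_with_column_name(self, captive_features):
        df = captive_features.copy()
        df.loc[df.index[3], "q_mean"] = np.nan
        cfg = clf.TrainConfig(
            parameter_grid={"max_depth": (3,)}, cv_folds=3, seed=0
        )
        with pytest.raises(ValueError, match="q_mean"):
            clf.train_gbm(df, cfg)

    def test_single_class_rejected(self, captive_features):
        df = captive_features.copy()
        df["label"] = "resting"
        cfg = clf.TrainConfig(parameter_grid={"max_depth": (3,)}, seed=0)
        with pytest.raises(ValueError, match="2 behaviour classes"):
            clf.train_gbm(df, cfg)


class TestPredictEpochs:
    def test_probabilities_on_simplex(self, trained_model, captive_features):
        model, _ = trained_model
        preds = clf.predict_epochs(model, captive_features)
        pcols = [f"p_{c}" for c in model.classes]
        probs = preds[pcols].to_numpy()
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (preds["predicted"] != preds["runner_up"]).all()

    def test_empty_input_gives_empty_output(self, trained_model, captive_features):
        model, _ = trained_model
        preds = clf.predict_epochs(model, captive_features.iloc[0:0])
        assert len(preds) == 0

    def test_training_pattern_predicted_as_its_label(
        self, trained_model, captive_features
    ):
        model, _ = trained_model
        # the strongest resting epochs should be called resting
        rest = captive_features[captive_features["label"] == "resting"]
        quiet = rest.nsmallest(10, "vedba_mean")
        preds = clf.predict_epochs(model, quiet)
        assert (preds["predicted"] == "resting").mean() >= 0.9

    def test_schema_mismatch_rejected(self, trained_model, captive_features):
        model, _ = trained_model
        broken = captive_features.drop(columns=["q_mean"])
        with pytest.raises((ValueError, KeyError)):
            clf.predict_epochs(model, broken)

    def test_round_trip_save_load_identical_predictions(
        self, trained_model, captive_features, tmp_path
    ):
        model, _ = trained_model
        p1 = model.predict_proba(captive_features)
        model.save(str(tmp_path / "m"))
        model2 = clf.BehaviourModel.load(str(tmp_path / "m"))
        p2 = model2.predict_proba(captive_features)
        np.testing.assert_array_equal(p1, p2)
        assert model2.classes == model.classes
        assert model2.feature_columns == model.feature_columns


class TestLowConfidenceAudit:
    def _preds(self, rows):
        cols = ["epoch_index", "start_s"] + [f"p_{b}" for b in BEHAVIOURS]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df:
                df[c] = 0.0
        return df

    def test_all_confident_gives_empty_table(self):
        preds = self._preds(
            [{"predicted": "resting", "runner_up": "grooming", "max_prob": 0.95}]
        )
        out = clf.low_confidence_audit(preds)
        assert len(out) == 0

    def test_single_low_confidence_epoch_tabulated(self):
        preds = self._preds(
            [
                {"predicted": "foraging", "runner_up": "travelling", "max_prob": 0.55},
                {"predicted": "resting", "runner_up": "grooming", "max_prob": 0.99},
            ]
        )
        out = clf.low_confidence_audit(preds)
        assert len(out) == 1
        assert tuple(out.iloc[0][["predicted", "runner_up", "count"]]) == (
            "foraging", "travelling", 1,
        )

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            clf.low_confidence_audit(pd.DataFrame())

    def test_low_confidence_fraction_is_a_proportion(
        self, trained_model, captive_features
    ):
        model, _ = trained_model
        preds = clf.predict_epochs(model, captive_features)
        frac = (preds["max_prob"] < 0.8).mean()
        assert 0.0 <= frac <= 1.0
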