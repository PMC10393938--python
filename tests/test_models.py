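"""Classifiers, metrics, and the evaluation protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecglvh import clinical, synth
from ecglvh.models import (
    LvhClassificationModel,
    classification_metrics,
    evaluate,
    rank_auc,
    train_logistic,
    train_rf,
    train_svm,
)


def brute_force_auc(labels, scores):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in
               itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRankAuc:
    def test_equals_concordant_pair_fraction(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 150)
        s = rng.normal(size=150)
        assert rank_auc(y, s) == pytest.approx(brute_force_auc(y, s),
                                               abs=1e-12)

    def test_with_ties(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 120)
        s = rng.integers(0, 5, 120).astype(float)  # heavy ties
        assert rank_auc(y, s) == pytest.approx(brute_force_auc(y, s),
                                               abs=1e-12)

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        assert rank_auc(y, y.astype(float)) == 1.0


class TestMetrics:
    def test_all_positive_predictor(self):
        y = np.array([1] * 10 + [0] * 90)
        m = classification_metrics(y, np.ones(100))
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_confusion_identities(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        m = classification_metrics(y, s)
        c = m["confusion"]
        assert m["sensitivity"] == c["tp"] / (c["tp"] + c["fn"])
        assert m["specificity"] == c["tn"] / (c["tn"] + c["fp"])
        assert c["tp"] + c["tn"] + c["fp"] + c["fn"] == 200

    def test_record_order_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        perm = rng.permutation(100)
        m1 = classification_metrics(y, s)
        m2 = classification_metrics(y[perm], s[perm])
        assert m1["auc"] == m2["auc"] and m1["accuracy"] == m2["accuracy"]


class TestTrainers:
    def test_logistic_separable_perfect_training_accuracy(self):
        X = np.vstack([np.full((20, 2), -2.0), np.full((20, 2), 2.0)])
        y = np.array([0] * 20 + [1] * 20)
        clf = train_logistic(X, y)
        assert (clf.predict(X) == y).all()

    def test_svm_solves_xor(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (400, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        clf = train_svm(X[:300], y[:300], seed=0)
        m = evaluate(clf, X[300:], y[300:])
        assert m["accuracy"] > 0.9  # a linear model cannot exceed ~0.5

    def test_rf_recovers_threshold_rule(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (400, 3))
        y = (X[:, 1] > 0.6).astype(int)
        clf = train_rf(X[:300], y[:300], seed=0)
        m = evaluate(clf, X[300:], y[300:])
        assert m["accuracy"] > 0.95

    def test_rf_seeded_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] + rng.normal(0, 0.5, 200) > 0).astype(int)
        p1 = train_rf(X, y, seed=7).predict_proba(X)[:, 1]
        p2 = train_rf(X, y, seed=7).predict_proba(X)[:, 1]
        np.testing.assert_array_equal(p1, p2)

    def test_bagging_reduces_prediction_variance(self):
        # variance of the ensemble mean over bootstrap refits is below
        # the variance of a single tree's prediction
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.tree import DecisionTreeClassifier
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 3))
        y = (X[:, 0] + rng.normal(0, 1.0, 300) > 0).astype(int)
        X_query = rng.normal(size=(25, 3))
        tree_preds, forest_preds = [], []
        for b in range(12):
            idx = rng.integers(0, 300, 300)
            tree = DecisionTreeClassifier(random_state=b).fit(X[idx], y[idx])
            forest = RandomForestClassifier(n_estimators=50, random_state=b
                                            ).fit(X[idx], y[idx])
            tree_preds.append(tree.predict_proba(X_query)[:, 1])
            forest_preds.append(forest.predict_proba(X_query)[:, 1])
        var_tree = np.var(np.array(tree_preds), axis=0).mean()
        var_forest = np.var(np.array(forest_preds), axis=0).mean()
        assert var_forest < var_tree


@pytest.fixture(scope="module")
def model_cohort():
    df = synth.generate_cohort(synth.CohortSpec(n=6000, seed=21))
    df = clinical.derive_covariates(df)
    return clinical.encode_model_features(df)


class TestLvhClassificationModel:
    def test_fit_returns_complete_results(self, model_cohort):
        model = LvhClassificationModel(
            model_cohort, synth.ECG_FEATURES + clinical.CLINICAL_FEATURES)
        res = model.fit(method="logistic", seed=0, do_cv=True)
        assert 0.0 <= res.auc <= 1.0
        assert res.cv_metrics is not None and len(res.cv_metrics) >= 5
        assert res.coefficients is not None
        assert "LVH classification" in res.summary()
        d = res.to_dict()
        assert d["metrics"]["auc"] == res.auc

    def test_null_cohort_auc_near_chance(self):
        df = synth.generate_cohort(
            synth.CohortSpec(n=6000, beta_qrs=0.0, beta_sbp=0.0,
                             lvh_qrs_boost=1.0, lvh_effect_scale=0.0,
                             seed=13))
        df = clinical.encode_model_features(clinical.derive_covariates(df))
        model = LvhClassificationModel(df, synth.ECG_FEATURES)
        res = model.fit(method="logistic", seed=0, do_cv=False)
        assert 0.3 <= res.auc <= 0.7

    def test_seeded_fit_reproducible(self, model_cohort):
        model = LvhClassificationModel(model_cohort, synth.ECG_FEATURES)
        r1 = model.fit(method="logistic", seed=5, do_cv=False)
        r2 = model.fit(method="logistic", seed=5, do_cv=False)
        assert r1.metrics == r2.metrics
        pd.testing.assert_series_equal(r1.coefficients, r2.coefficients)

    def test_centre_rotation_shape_and_refit(self, model_cohort):
        model = LvhClassificationModel(
            model_cohort, synth.ECG_FEATURES + clinical.CLINICAL_FEATURES)
        rot = model.centre_rotation(method="logistic", seed=0)
        assert len(rot) == 3
        assert rot["test_centres"].tolist() == [
            "Reading+Bristol", "Cheadle", "Newcastle"]
        assert (rot["auc"] > 0.6).all()
        assert (rot["train_lvh"] + rot["test_lvh"]
                == model_cohort["lvh"].sum()).all()

    def test_empty_centre_partition_raises(self, model_cohort):
        df = model_cohort[model_cohort["centre"] != "Newcastle"]
        model = LvhClassificationModel(
            df.reset_index(drop=True), synth.ECG_FEATURES)
        with pytest.raises(ValueError):
            model.centre_rotation(method="logistic", seed=0)

    def test_missing_feature_column_raises(self, model_cohort):
        with pytest.raises(KeyError):
            LvhClassificationModel(model_cohort, ["not_a_column"])

    def test_roc_points_integrate_to_rank_auc(self, model_cohort):
        # trapezoidal area under the empirical ROC equals the rank AUC
        model = LvhClassificationModel(model_cohort, synth.ECG_FEATURES)
        res = model.fit(method="logistic", seed=2, do_cv=False)
        pts = res.roc_points()
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        assert area == pytest.approx(res.auc, abs=1e-9)
        assert pts.iloc[0]["tpr"] == 0.0 and pts.iloc[-1]["tpr"] == 1.0
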