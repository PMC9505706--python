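import numpy as np
import pandas as pd
import pytest

from taxrisk.errors import ConfigError, ValidationError
from taxrisk.risk_model import (
    ModelBundle,
    align_features,
    cross_validate,
    fit_gbm,
    importance,
    operating_point,
    roc_auc,
    score_cohort,
    select_features,
)
from taxrisk.taxa_io import SampleMetadata

FAST_HP = {"n_estimators": 50}


@pytest.fixture
def separable():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(0, 1, (40, 2)), columns=["a", "b"])
    y = (X["a"] > 0).astype(float).to_numpy()
    X.loc[:, "a"] += y * 5  # wide margin
    return X, y


class TestSelectFeatures:
    def test_constant_zero_dropped_informative_kept(self):
        rng = np.random.default_rng(1)
        informative = rng.random((20, 50))
        zeros = np.zeros((20, 50))
        df = pd.DataFrame(np.hstack([informative, zeros]))
        df.columns = [f"f{j}" for j in range(100)]
        out = select_features(df)
        assert out.shape[1] == 50

    def test_single_presence_retained(self):
        df = pd.DataFrame({"once": [0, 0, 0.4], "never": [0, 0, 0]})
        out = select_features(df)
        assert list(out.columns) == ["once"]

    def test_nothing_retained_errors(self):
        with pytest.raises(ValidationError):
            select_features(pd.DataFrame({"z": [0.0, 0.0]}))


class TestFitGbm:
    def test_separable_training_auc_is_one(self, separable):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=0)
        auc, _ = roc_auc(bundle.predict(X), y)
        assert auc == 1.0

    def test_refit_reproduces_predictions(self, separable):
        X, y = separable
        p1 = fit_gbm(X, y, FAST_HP, seed=3).predict(X)
        p2 = fit_gbm(X, y, FAST_HP, seed=3).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_duplicated_rows_identical_predictions(self, separable):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=0)
        X2 = pd.concat([X, X])
        preds = bundle.predict(X2)
        np.testing.assert_array_equal(preds[:40], preds[40:])

    def test_single_class_errors(self, separable):
        X, _ = separable
        with pytest.raises(ValidationError):
            fit_gbm(X, np.zeros(len(X)), FAST_HP)

    def test_persistence_roundtrip_bitwise(self, separable, tmp_path):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=5)
        bundle.save(tmp_path / "model")
        again = ModelBundle.load(tmp_path / "model")
        np.testing.assert_array_equal(bundle.predict(X), again.predict(X))
        assert again.feature_names == bundle.feature_names


class TestRocAndOperatingPoint:
    def test_four_sample_example(self):
        auc, curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)
        op = operating_point(curve)
        assert op["sensitivity"] == pytest.approx(0.5)
        assert op["specificity"] == pytest.approx(1.0)
        assert 0.4 < op["threshold"] <= 0.8

    def test_perfect_ordering(self):
        auc, curve = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        op = operating_point(curve)
        assert op["sensitivity"] == 1.0 and op["specificity"] == 1.0

    def test_all_tied_scores(self):
        auc, curve = roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert auc == 0.5
        op = operating_point(curve)
        assert op["youden_j"] == pytest.approx(0.0)
        assert (op["sensitivity"], op["specificity"]) in ((0.0, 1.0), (1.0, 0.0))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(np.exp(5 * s) + 3, y)
        assert a1 == pytest.approx(a2)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCrossValidate:
    def test_null_labels_auc_near_half(self, separable):
        X, y = separable
        rng = np.random.default_rng(4)
        cv = cross_validate(X, rng.permutation(y), n_iter=10,
                            base_seed=0, hyperparams=FAST_HP)
        assert 0.2 <= cv.summary()["mean_auc"] <= 0.8  # small-n null

    def test_signal_recovered(self, separable):
        X, y = separable
        cv = cross_validate(X, y, n_iter=5, base_seed=0, hyperparams=FAST_HP)
        assert cv.summary()["mean_auc"] > 0.9

    def test_summary_recomputable_and_n_iter_one(self, separable):
        X, y = separable
        cv = cross_validate(X, y, n_iter=1, base_seed=7, hyperparams=FAST_HP)
        s = cv.summary()
        assert s["mean_auc"] == cv.iterations[0]["auc"]
        assert s["sd_auc"] == 0.0
        cv5 = cross_validate(X, y, n_iter=5, base_seed=7, hyperparams=FAST_HP)
        aucs = cv5.aucs
        s5 = cv5.summary()
        assert s5["mean_auc"] == pytest.approx(aucs.mean())
        assert s5["sd_auc"] == pytest.approx(aucs.std(ddof=1))
        assert s5["min_auc"] == aucs.min() and s5["max_auc"] == aucs.max()

    def test_stratification_preserves_class_ratio(self, separable):
        X, y = separable
        cv = cross_validate(X, y, n_iter=5, base_seed=1, hyperparams=FAST_HP)
        for it in cv.iterations:
            tr = y[it["train_idx"]]
            assert abs(tr.mean() - y.mean()) <= 1.5 / len(tr) + 0.05


class TestImportance:
    def test_single_informative_feature_dominates(self, separable):
        X, y = separable
        X = X.copy()
        X["b"] = 0.0  # kill the second feature
        bundle = fit_gbm(X[["a"]], y, FAST_HP, seed=0)
        imp = importance(bundle, "impurity")
        assert imp.loc["a", "importance"] == pytest.approx(1.0)

    def test_impurity_sums_to_one(self, separable):
        X, y = separable
        imp = importance(fit_gbm(X, y, FAST_HP, seed=0), "impurity")
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp["importance"] >= 0).all()

    def test_permutation_irrelevant_feature_near_zero(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(0, 1, (120, 3)),
                         columns=["signal", "noise1", "noise2"])
        y = (X["signal"] + rng.normal(0, 0.3, 120) > 0).astype(float)
        bundle = fit_gbm(X.iloc[:80], y[:80], FAST_HP, seed=0)
        imp = importance(bundle, "permutation", data=X.iloc[80:],
                         labels=y[80:], n_repeats=10, seed=0)
        assert abs(imp.loc["noise2", "importance"]) < 0.02
        assert imp.loc["signal", "importance"] > 0.1

    def test_permutation_without_data_errors(self, separable):
        X, y = separable
        with pytest.raises(ConfigError):
            importance(fit_gbm(X, y, FAST_HP), "permutation")


class TestTransfer:
    def test_identity_alignment(self, separable):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=0)
        aligned, cov = align_features(bundle, X)
        assert cov == 1.0
        pd.testing.assert_frame_equal(aligned, X)

    def test_missing_features_zero_filled(self, separable):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=0)
        aligned, cov = align_features(bundle, X[["a"]])
        assert cov == 0.5
        assert (aligned["b"] == 0).all()

    def test_extra_features_dropped_and_zero_coverage_errors(self, separable):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=0)
        Xext = X.copy()
        Xext["junk"] = 1.0
        aligned, _ = align_features(bundle, Xext)
        assert "junk" not in aligned.columns
        with pytest.raises(ValidationError):
            align_features(bundle, pd.DataFrame({"other": [1.0]}))

    def test_training_controls_score_below_threshold(self, separable):
        X, y = separable
        bundle = fit_gbm(X, y, FAST_HP, seed=0)
        meta = SampleMetadata({str(i): ("case" if v else "ctrl")
                               for i, v in enumerate(y)})
        X2 = X.copy()
        X2.index = [str(i) for i in range(len(X))]
        result = score_cohort(bundle, X2, meta)
        ctrl_scores = result.scores[result.groups == "ctrl"]
        assert (np.clip(ctrl_scores, 0, 1) < 0.5).mean() > 0.5
        assert set(result.pairwise_tests.columns) >= {
            "group_a", "group_b", "U", "p_value", "adjusted_p"}
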