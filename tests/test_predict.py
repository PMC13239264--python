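"""Tests for the nested-CV prediction benchmark and its metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import brier_score_loss, roc_auc_score

from mspira.predict import (
    DEMOGRAPHIC_COLS,
    MODEL_SPECS,
    ModelSpec,
    Preprocessor,
    PredictorSetSpec,
    auc,
    brier_score,
    calibration_bins,
    make_predictor_sets,
    nested_cv_evaluate,
    preprocess_fit_apply,
)


class TestMetrics:
    def test_brier_hand_examples(self):
        assert brier_score([1.0, 0.0], [1, 0]) == 0.0
        assert brier_score([0.5, 0.5], [1, 0]) == 0.25
        assert brier_score([0.8, 0.2], [1, 0]) == pytest.approx(0.04)

    def test_brier_length_mismatch(self):
        with pytest.raises(ValueError):
            brier_score([0.5], [1, 0])

    def test_auc_hand_examples(self):
        assert auc([0.9, 0.1], [1, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5], [1, 0, 1]) == 0.5  # ties -> chance
        assert auc([0.8, 0.6, 0.4], [1, 0, 1]) == 0.5  # one concordant, one discordant pair

    def test_auc_single_class_undefined(self):
        with pytest.raises(ValueError):
            auc([0.5, 0.6], [1, 1])

    def test_metrics_match_sklearn(self):
        rng = np.random.default_rng(0)
        p = rng.random(300)
        y = (rng.random(300) < p).astype(int)
        assert auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)
        assert brier_score(p, y) == pytest.approx(brier_score_loss(y, p), abs=1e-12)


class TestCalibrationBins:
    def test_edges_from_positives_only(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        full = calibration_bins(p, y, n_bins=5)
        # removing negatives does not change the bin edges
        pos_only = calibration_bins(p[y == 1], y[y == 1], n_bins=5)
        np.testing.assert_allclose(full["bin_low"], pos_only["bin_low"])
        np.testing.assert_allclose(full["bin_high"], pos_only["bin_high"])

    def test_calibrated_probs_match_observed(self):
        rng = np.random.default_rng(2)
        p = rng.random(6000)
        y = (rng.random(6000) < p).astype(int)
        tab = calibration_bins(p, y, n_bins=10)
        ok = tab.dropna()
        err = (ok["mean_predicted"] - ok["observed_rate"]).abs()
        binom_se = np.sqrt(ok["mean_predicted"] * (1 - ok["mean_predicted"]) / ok["n"])
        assert (err < 4 * binom_se + 0.02).all()

    def test_all_positives_one_prob_collapses(self):
        p = np.array([0.3, 0.3, 0.1, 0.9])
        y = np.array([1, 1, 0, 0])
        tab = calibration_bins(p, y, n_bins=10)
        assert len(tab) == 1

    def test_needs_a_positive(self):
        with pytest.raises(ValueError):
            calibration_bins([0.2, 0.4], [0, 0])


def _toy_features(n=80, seed=0, with_missing=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age_at_start": rng.normal(40, 10, n),
            "sex": rng.choice(["female", "male"], n),
            "born_in_country": rng.integers(0, 2, n).astype(float),
            "income": rng.normal(200, 60, n),
            "education": rng.choice(["primary", "secondary", "higher"], n),
            "area": rng.choice(["A", "B", "C"], n),
        }
    )
    if with_missing:
        df.loc[rng.random(n) < 0.25, "income"] = np.nan
    return df


class TestPredictorSets:
    def test_nesting_and_icd_placement(self, demo_bundle):
        cols = list(_toy_features().columns) + [
            "therapy_start_year", "years_since_onset", "n_prior_dmts",
            "n_prior_relapses", "baseline_edss", "sdmt", "msis_physical",
            "msis_psychological", "depression_anxiety", "hypertension",
            "icd_N31", "icd_M54",
        ]
        feats = pd.DataFrame(np.zeros((3, len(cols))), columns=cols)
        sets = make_predictor_sets(feats, icd_columns=("icd_N31", "icd_M54"))
        names = [s.name for s in sets]
        assert names == ["demographics", "ms_characteristics", "prespecified", "data_driven"]
        assert len(sets[0].columns) == 6
        for smaller, larger in zip(sets, sets[1:]):
            assert set(smaller.columns) < set(larger.columns)
        assert "icd_N31" in sets[3].columns
        for s in sets[:3]:
            assert not any(c.startswith("icd_") for c in s.columns)

    def test_missing_column_rejected(self):
        feats = pd.DataFrame({"age_at_start": [1.0]})
        with pytest.raises(ValueError):
            make_predictor_sets(feats, icd_columns=())


class TestPreprocessor:
    def test_train_statistics_reused_on_test(self):
        train = _toy_features(seed=1)
        test = _toy_features(seed=2)
        y_tr = np.zeros(len(train))
        a, b, prep = preprocess_fit_apply(train, y_tr, test)
        # train numerics are standardized against train stats...
        assert a["age_at_start"].mean() == pytest.approx(0.0, abs=1e-9)
        # ...and the same (train) stats are applied to the test partition
        expected = (test["age_at_start"] - train["age_at_start"].mean()) / train[
            "age_at_start"
        ].std(ddof=0)
        np.testing.assert_allclose(b["age_at_start"], expected)
        assert abs(b["age_at_start"].mean()) > 1e-6  # not re-centred on itself

    def test_no_missing_imputer_is_identity(self):
        train = _toy_features(seed=3)
        a, _, prep = preprocess_fit_apply(train, np.zeros(len(train)), train)
        assert prep._imputers == {}

    def test_binary_nominal_one_dummy_when_full_rank(self):
        train = _toy_features(seed=4)
        a, _, _ = preprocess_fit_apply(train, np.zeros(len(train)), train, drop_first=True)
        sex_cols = [c for c in a.columns if c.startswith("sex__")]
        assert len(sex_cols) == 1

    def test_unseen_category_maps_to_zero_block(self):
        train = _toy_features(seed=5)
        test = _toy_features(seed=6)
        test.loc[0, "area"] = "Z_unseen"
        _, b, _ = preprocess_fit_apply(train, np.zeros(len(train)), test)
        area_cols = [c for c in b.columns if c.startswith("area__")]
        assert b.loc[0, area_cols].sum() == 0.0

    def test_bagged_imputation_uses_covariates(self):
        rng = np.random.default_rng(7)
        n = 400
        train = _toy_features(n, seed=7)
        train["income"] = 5.0 * train["age_at_start"] + rng.normal(0, 5, n)
        miss = rng.random(n) < 0.3
        observed = train["income"].copy()
        train.loc[miss, "income"] = np.nan
        a, _, _ = preprocess_fit_apply(train, np.zeros(n), train)
        # standardization is monotone, so correlation is scale-free
        corr = np.corrcoef(a.loc[miss, "income"], observed[miss])[0, 1]
        assert corr > 0.9


class TestNestedCV:
    def test_separable_feature_gives_high_auc(self):
        rng = np.random.default_rng(8)
        n = 150
        feats = _toy_features(n, seed=8)
        y = rng.integers(0, 2, n)
        feats["age_at_start"] = y * 10.0 + rng.normal(0, 0.5, n)
        spec = PredictorSetSpec("demographics", tuple(feats.columns))
        model = ModelSpec("elastic_net", {}, {"penalty": (1e-3,), "mixture": (0.0,)})
        ev = nested_cv_evaluate(feats, y, model, spec, outer=(5, 1), inner=3, seed=0)
        assert ev.auc_mean > 0.95 and ev.brier_mean < 0.1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        n = 120
        feats = _toy_features(n, seed=9, with_missing=True)
        y = rng.integers(0, 2, n)
        spec = PredictorSetSpec("demographics", tuple(feats.columns))
        model = ModelSpec(
            "elastic_net", {}, {"penalty": (1e-3, 1e-1), "mixture": (0.0, 1.0)}
        )
        e1 = nested_cv_evaluate(feats, y, model, spec, outer=(4, 1), inner=3, seed=5)
        e2 = nested_cv_evaluate(feats, y, model, spec, outer=(4, 1), inner=3, seed=5)
        assert e1.fold_auc == e2.fold_auc and e1.fold_brier == e2.fold_brier
        assert e1.tuning_trace == e2.tuning_trace

    def test_corrupting_test_labels_leaves_fit_unchanged(self):
        """Leakage guard: preprocessing is fitted on the training partition
        only, so corrupting test labels changes neither the fitted
        parameters nor (absent test-side missingness) the transformed
        output; the tuning trace is a deterministic function of the
        training data."""
        rng = np.random.default_rng(10)
        n = 120
        feats = _toy_features(n, seed=10, with_missing=True)
        test = _toy_features(40, seed=12)  # complete test partition
        y_tr = rng.integers(0, 2, n)
        y_te = rng.integers(0, 2, 40)
        _, out_honest, prep1 = preprocess_fit_apply(feats, y_tr, test, y_te)
        _, out_corrupt, prep2 = preprocess_fit_apply(feats, y_tr, test, 1 - y_te)
        pd.testing.assert_series_equal(prep1._means, prep2._means)
        pd.testing.assert_series_equal(prep1._sds, prep2._sds)
        assert prep1._categories == prep2._categories
        pd.testing.assert_frame_equal(out_honest, out_corrupt)

        spec = PredictorSetSpec("demographics", tuple(feats.columns))
        model = ModelSpec(
            "elastic_net", {}, {"penalty": (1e-3, 1e-1), "mixture": (0.0, 1.0)}
        )
        baseline = nested_cv_evaluate(feats, y_tr, model, spec, outer=(4, 1), inner=3, seed=5)
        rerun = nested_cv_evaluate(feats, y_tr, model, spec, outer=(4, 1), inner=3, seed=5)
        assert baseline.tuning_trace == rerun.tuning_trace

    @pytest.mark.parametrize("family", ["random_forest", "xgboost", "neural_net"])
    def test_all_families_run(self, family):
        rng = np.random.default_rng(11)
        n = 100
        feats = _toy_features(n, seed=11)
        y = (feats["age_at_start"] > 40).astype(int).to_numpy()
        spec = PredictorSetSpec("demographics", tuple(feats.columns))
        base = MODEL_SPECS[family]
        fixed = dict(base.fixed)
        if "n_trees" in fixed:
            fixed["n_trees"] = 50  # scaled down for unit-test speed
        model = ModelSpec(family, fixed, {k: (v[0],) for k, v in base.grid.items()})
        ev = nested_cv_evaluate(feats, y, model, spec, outer=(3, 1), inner=2, seed=1)
        assert 0.5 < ev.auc_mean <= 1.0

    def test_grid_is_full_factorial_four_levels(self):
        for fam, spec in MODEL_SPECS.items():
            for values in spec.grid.values():
                assert len(values) == 4, fam
            assert len(spec.configurations()) == 4 ** len(spec.grid)
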