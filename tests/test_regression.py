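"""Diagnosis regression: OLS inference against statsmodels, the sign rule,
confusion metrics, cross-validation determinism and leak-freedom, and the
feature-count sweep."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import gaitdx.regression as reg
from gaitdx import (
    ConfusionCounts,
    CVConfig,
    DiagnosisModel,
    GaitdxError,
    SingularDesignError,
    classification_metrics,
    classify,
    confusion_from_predictions,
    cross_validate,
    feature_contributions,
    feature_sweep,
    fit_ols,
    format_percent,
    predict_outcome,
)
from gaitdx.errors import GaitdxWarning
from gaitdx.preprocess import relabel
from gaitdx.worked_example import (
    ACLD_SUBJECT,
    CONTROL_SUBJECT,
    reference_model,
)


class TestFitOls:
    def test_intercept_only_model(self, rng):
        y = np.array([1.0, 1, -1, 1, -1])
        model = fit_ols(np.empty((5, 0)), y)
        assert model.intercept == pytest.approx(y.mean())
        assert model.r_squared == pytest.approx(0.0)

    def test_perfect_linear_fit(self, rng):
        x = rng.normal(size=20)
        y = 2.0 + 3.0 * x
        model = fit_ols(x[:, None], y)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.rmse == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(model.coefficients, [2.0, 3.0], atol=1e-10)

    def test_matches_statsmodels_inference(self, rng):
        X = rng.normal(size=(43, 6))
        y = np.where(rng.random(43) < 0.6, 1.0, -1.0)
        model = fit_ols(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(model.coefficients, ref.params, atol=1e-8)
        np.testing.assert_allclose(model.std_errors, ref.bse, atol=1e-8)
        np.testing.assert_allclose(model.p_values, ref.pvalues, atol=1e-8)
        assert model.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
        assert model.f_pvalue == pytest.approx(ref.f_pvalue, abs=1e-10)
        assert model.rmse == pytest.approx(np.sqrt(ref.mse_resid), abs=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = fit_ols(X, y)
        D = np.column_stack([np.ones(30), X])
        resid = y - D @ model.coefficients
        assert np.abs(resid @ D).max() / max(np.abs(y).max(), 1) < 1e-8

    def test_r_squared_matches_independent_sse_sst(self, rng):
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=25)
        model = fit_ols(X, y)
        D = np.column_stack([np.ones(25), X])
        sse = ((y - D @ model.coefficients) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert model.r_squared == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_collinear_design_names_columns(self, rng):
        x = rng.normal(size=20)
        table = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=20)})
        with pytest.raises(SingularDesignError) as err:
            fit_ols(table, rng.normal(size=20))
        assert err.value.collinear_columns

    def test_model_json_round_trip(self, rng):
        model = fit_ols(rng.normal(size=(20, 3)), rng.normal(size=20))
        restored = DiagnosisModel.from_json(model.to_json())
        np.testing.assert_array_equal(restored.coefficients, model.coefficients)
        assert restored.feature_names == model.feature_names


class TestPredictAndClassify:
    def test_published_worked_example(self):
        model = reference_model()
        assert round(predict_outcome(model, ACLD_SUBJECT), 4) == 0.6164
        assert round(predict_outcome(model, CONTROL_SUBJECT), 4) == -0.4672

    def test_zero_features_give_intercept(self):
        model = reference_model()
        assert predict_outcome(model, np.zeros(6)) == pytest.approx(0.1628)

    @pytest.mark.parametrize(
        "score, expected",
        [(0.6164, "ACLD"), (-0.4672, "CONTROL"), (0.0, "CONTROL")],
    )
    def test_sign_rule(self, score, expected):
        assert classify(score) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(GaitdxError):
            classify(float("nan"))

    def test_contributions_sum_to_outcome(self):
        model = reference_model()
        contrib = feature_contributions(model, ACLD_SUBJECT)
        assert contrib.sum() == pytest.approx(
            predict_outcome(model, ACLD_SUBJECT), abs=1e-12
        )


class TestClassificationMetrics:
    def test_published_confusion_counts(self):
        m = classification_metrics(ConfusionCounts(TP=20, FP=3, FN=5, TN=15))
        assert format_percent(m["accuracy"]) == "81.4%"
        assert format_percent(m["precision"]) == "87.0%"
        assert format_percent(m["recall"]) == "80.0%"
        assert format_percent(m["specificity"]) == "83.3%"
        assert format_percent(m["f1"]) == "83.3%"

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(TP=10, FP=0, FN=0, TN=10))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_precision_nan_with_warning(self):
        with pytest.warns(GaitdxWarning):
            m = classification_metrics(ConfusionCounts(TP=0, FP=0, FN=5, TN=5))
        assert np.isnan(m["precision"]) and m["recall"] == 0.0

    def test_identities(self, rng):
        c = ConfusionCounts(*rng.integers(1, 30, size=4))
        m = classification_metrics(c)
        assert m["accuracy"] * c.total == pytest.approx(c.TP + c.TN)
        assert m["f1"] == pytest.approx(
            2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        )

    def test_all_zero_rejected(self):
        with pytest.raises(GaitdxError):
            classification_metrics(ConfusionCounts())


class TestCrossValidate:
    def test_deterministic_given_seed(self, small_cohort):
        a = cross_validate(small_cohort, CVConfig(seed=7, k_folds=4))
        b = cross_validate(small_cohort, CVConfig(seed=7, k_folds=4))
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        assert a.accuracy == b.accuracy

    def test_folds_partition_cohort(self, small_cohort):
        result = cross_validate(small_cohort, CVConfig(seed=3, k_folds=4))
        assert (result.fold_assignments >= 0).all()
        assert result.pooled.total == len(small_cohort)
        assert sum(c.total for c in result.per_fold) == len(small_cohort)

    def test_separable_cohort_perfect_accuracy(self, small_cohort):
        # amplify separation: relabel by the sign of a strongly shifted signal
        spec_cohort = small_cohort
        for mode in ("refit_all", "reuse_features"):
            result = cross_validate(
                spec_cohort, CVConfig(seed=0, k_folds=4, leakage_mode=mode)
            )
            assert result.accuracy >= 0.8  # strong effect (d=1.5) cohort

    def test_refit_all_never_reads_test_rows_during_fit(
        self, small_cohort, monkeypatch
    ):
        accessed_during_fit: set[str] = set()
        in_fit = [False]
        fit_access_per_call: list[set] = []
        train_sets: list[set] = []

        class Tracked(type(small_cohort[0])):
            def signal(self, name):
                if in_fit[0]:
                    accessed_during_fit.add(self.subject_id)
                return super().signal(name)

        tracked = [
            Tracked(pw.subject_id, pw.group, pw.leg, pw.values)
            for pw in small_cohort
        ]
        orig = reg._assemble

        def spy(cohort, config):
            in_fit[0] = True
            try:
                return orig(cohort, config)
            finally:
                in_fit[0] = False
                fit_access_per_call.append(set(accessed_during_fit))
                accessed_during_fit.clear()
                train_sets.append({pw.subject_id for pw in cohort})

        monkeypatch.setattr(reg, "_assemble", spy)
        cross_validate(tracked, CVConfig(seed=2, k_folds=4))
        assert len(fit_access_per_call) == 4
        for used, allowed in zip(fit_access_per_call, train_sets):
            assert used <= allowed, "fit phase read subjects outside its fold"
            assert used  # the fit did read its training rows

    def test_missing_class_raises(self, small_cohort):
        acld = [pw for pw in small_cohort if pw.group == "ACLD"]
        bad = acld + [relabel(small_cohort[-1], "CONTROL")]
        with pytest.raises(GaitdxError):
            cross_validate(bad, CVConfig(seed=0, k_folds=5, stratified=True))


class TestFeatureSweep:
    def test_sweep_rows_and_determinism(self, small_cohort):
        sweep_spec = (("full", 0), ("full", 1), ("composite_only", 2))
        cfg = CVConfig(seed=4, k_folds=4)
        a = feature_sweep(small_cohort, sweep_spec, cfg)
        b = feature_sweep(small_cohort, sweep_spec, cfg)
        assert list(a["features"]) == ["3 + 0", "3 + 1", "0 + 2"]
        pd.testing.assert_frame_equal(a, b)
        assert ((a["accuracy"] >= 0) & (a["accuracy"] <= 1)).all()
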