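"""Split arithmetic, standardization, MI selection, search, and reports."""

import numpy as np
import pandas as pd
import pytest

from thermoleaf.classify import (
    EvalReport,
    PipelineConfig,
    SplitSpec,
    compare_models,
    evaluate,
    f1_from_precision_recall,
    select_features_mi,
    split_dataset,
    standardize,
    tune_and_train,
)

COHORT_LABELS = np.array(["WW"] * 212 + ["DD"] * 207)  # the study's class sizes


class TestSplit:
    def test_study_size_split(self):
        """419 samples at 75/25 give |T|=314 and |V|=105."""
        t, v = split_dataset(COHORT_LABELS, SplitSpec(train_fraction=0.75, seed=0))
        assert len(t) == 314
        assert len(v) == 105
        assert len(np.intersect1d(t, v)) == 0
        assert len(np.union1d(t, v)) == 419

    def test_floor_arithmetic_tiny(self):
        t, v = split_dataset(
            ["WW", "WW", "DD", "DD"],
            SplitSpec(train_fraction=0.75, stratified=False),
        )
        assert len(t) == 3 and len(v) == 1

    def test_stratification_impossible_at_tiny_n(self):
        with pytest.raises(ValueError, match="stratif"):
            split_dataset(["WW", "WW", "DD", "DD"], SplitSpec(train_fraction=0.75))

    def test_deterministic_per_seed(self):
        a = split_dataset(COHORT_LABELS, SplitSpec(seed=3))
        b = split_dataset(COHORT_LABELS, SplitSpec(seed=3))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_stratification_preserves_balance(self):
        t, v = split_dataset(COHORT_LABELS, SplitSpec(seed=0))
        ww_frac_t = (COHORT_LABELS[t] == "WW").mean()
        ww_frac_v = (COHORT_LABELS[v] == "WW").mean()
        assert abs(ww_frac_t - ww_frac_v) < 0.02


class TestStandardize:
    def test_train_column_to_unit_normal(self):
        out, _, params = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert out.mean() == pytest.approx(0.0)
        assert out.std(ddof=1) == pytest.approx(1.0)
        assert params.mean[0] == 2.0

    def test_validation_value_at_train_mean_maps_to_zero(self):
        _, applied, _ = standardize(
            np.array([[1.0], [2.0], [3.0]]), apply_to=np.array([[2.0]])
        )
        assert applied[0, 0] == 0.0

    def test_constant_column_centered_with_warning(self):
        train = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out, _, params = standardize(train)
        np.testing.assert_array_equal(out[:, 0], 0.0)
        assert params.constant_columns == (0,)


class TestFeatureSelection:
    def test_k_equals_all_is_identity(self, rng):
        X = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 50)
        assert select_features_mi(X, y, k=4) == list("abcd")

    def test_k_too_large_rejected(self, rng):
        X = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            select_features_mi(X, np.zeros(20), k=5)

    def test_informative_features_selected(self):
        """Only two columns carry the class signal; k=2 must pick them in
        nearly every seeded repetition."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 40)
            X = pd.DataFrame(
                {
                    "mean": y * 2.0 + rng.normal(0, 0.3, 80),
                    "noise1": rng.normal(size=80),
                    "median": y * 2.0 + rng.normal(0, 0.3, 80),
                    "noise2": rng.normal(size=80),
                }
            )
            if set(select_features_mi(X, y, k=2, seed=seed)) == {"mean", "median"}:
                hits += 1
        assert hits / reps >= 0.95


def _separable_dataset(seed=0, n=60, offset=4.0):
    rng = np.random.default_rng(seed)
    y = np.array(["WW"] * n + ["DD"] * n)
    shift = np.where(y == "DD", offset, 0.0)
    X = pd.DataFrame(
        {
            "mean": 27 + shift + rng.normal(0, 0.5, 2 * n),
            "median": 27 + shift + rng.normal(0, 0.5, 2 * n),
            "std": rng.normal(1, 0.2, 2 * n),
        }
    )
    return X, y


class TestTuneAndTrain:
    def test_degenerate_search_returns_fixed_point(self):
        """Collapsing the search space to a single point returns exactly the
        configured hyperparameters."""
        X, y = _separable_dataset()
        space = {
            "select__k": [3],
            "model__max_depth": [5],
            "model__min_samples_leaf": [5],
            "model__n_estimators": [100],
        }
        cfg = PipelineConfig(model="rf", search_space=space, cv_folds=5, seed=0)
        result = tune_and_train(X, y, cfg)
        assert result.best_params == {
            "select__k": 3,
            "model__max_depth": 5,
            "model__min_samples_leaf": 5,
            "model__n_estimators": 100,
        }

    def test_separable_data_high_cv_score(self):
        X, y = _separable_dataset(offset=5.0)
        cfg = PipelineConfig(model="rf", cv_folds=5, search_iterations=4, seed=1)
        result = tune_and_train(X, y, cfg)
        assert result.cv_score >= 0.95

    def test_deterministic_per_seed(self):
        X, y = _separable_dataset()
        cfg = PipelineConfig(model="rf", cv_folds=5, search_iterations=4, seed=2)
        a = tune_and_train(X, y, cfg)
        b = tune_and_train(X, y, cfg)
        assert a.best_params == b.best_params
        assert a.cv_score == b.cv_score

    def test_single_class_rejected(self):
        X, _ = _separable_dataset()
        with pytest.raises(ValueError, match="both classes"):
            tune_and_train(X, np.array(["WW"] * len(X)), PipelineConfig(model="rf"))


class TestEvalReport:
    def test_printed_mlp_counts_give_78_percent(self):
        """37 WW + 45 DD correct on 105 validation leaves → 78% accuracy."""
        report = EvalReport.from_counts(
            correct_dd=45, correct_ww=37, support_dd=52, support_ww=53
        )
        assert report.n_correct == 82
        assert round(100 * report.accuracy) == 78

    def test_printed_rf_counts_give_27_miscategorized(self):
        """40 WW + 38 DD correct on 105 validation leaves → 27 wrong."""
        report = EvalReport.from_counts(
            correct_dd=38, correct_ww=40, support_dd=51, support_ww=54
        )
        assert report.n_validation - report.n_correct == 27

    @pytest.mark.parametrize(
        "precision,recall,expected",
        [(0.78, 0.71, 0.74), (0.74, 0.87, 0.80), (0.84, 0.70, 0.76)],
    )
    def test_f1_from_precision_recall(self, precision, recall, expected):
        assert round(f1_from_precision_recall(precision, recall), 2) == expected

    def test_f1_zero_when_both_zero(self):
        assert f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_perfect_predictions(self):
        y = ["DD"] * 10 + ["WW"] * 10
        report = EvalReport.from_predictions(y, y)
        assert report.accuracy == 1.0
        assert report.confusion[0, 1] == report.confusion[1, 0] == 0
        for m in report.per_class.values():
            assert m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_report_text_rounding(self):
        report = EvalReport.from_counts(
            correct_dd=45, correct_ww=37, support_dd=52, support_ww=53, model="mlp"
        )
        text = report.to_text()
        assert "78%" in text
        assert "82/105" in text


class TestCompareModels:
    def test_printed_totals_delta(self):
        rf = EvalReport.from_counts(38, 40, 51, 54, model="rf")
        mlp = EvalReport.from_counts(45, 37, 52, 53, model="mlp")
        comp = compare_models(rf, mlp)
        assert comp["delta_correct_mlp_minus_rf"] == 4
        assert comp["delta_accuracy_points"] == pytest.approx(3.8, abs=0.05)
        assert comp["same_validation_size"]

    def test_identical_reports_zero_delta(self):
        r = EvalReport.from_counts(38, 40, 51, 54)
        comp = compare_models(r, r)
        assert comp["delta_correct_mlp_minus_rf"] == 0
        assert comp["delta_accuracy_points"] == 0.0

    def test_different_support_flagged(self):
        rf = EvalReport.from_counts(38, 40, 51, 54)
        mlp = EvalReport.from_counts(40, 40, 52, 54)
        assert not compare_models(rf, mlp)["same_validation_size"]
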