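import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from glioprep import (
    CLASSIFIER_FAMILIES,
    FeatureSetModel,
    balanced_accuracy,
    bootstrap_ci,
    cross_validate_models,
    factorial_anova_tukey,
    roc_auc,
)
from glioprep.features import FEATURE_NAMES, FIRST_ORDER_NAMES, TEXTURE_NAMES


def _synthetic_table(n_per_class=20, informative=True, seed=0):
    """A feature table whose grade is (optionally) encoded in one feature."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    rows = {
        "case_id": [f"c{i}" for i in range(n)],
        "grade": ["low"] * n_per_class + ["high"] * n_per_class,
        "scanner_id": ["s"] * n,
        "normalization": ["zscore"] * n,
        "mode": ["FBN"] * n,
        "bins": [32] * n,
    }
    for name in FEATURE_NAMES:
        rows[name] = rng.normal(size=n)
    if informative:
        rows["firstorder/Mean"] = np.r_[
            rng.normal(0, 0.3, n_per_class), rng.normal(4, 0.3, n_per_class)
        ]
    return pd.DataFrame(rows)


class TestBalancedAccuracy:
    def test_worked_confusion(self):
        conf = np.array([[30, 20], [10, 40]])  # TN FP / FN TP
        assert balanced_accuracy(conf) == pytest.approx(0.7)

    def test_perfect_and_majority(self):
        assert balanced_accuracy(np.array([[10, 0], [0, 5]])) == 1.0
        assert balanced_accuracy(np.array([[10, 0], [5, 0]])) == 0.5

    def test_absent_class_raises(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([[0, 0], [3, 7]]))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 2, 3, 10, 11]), np.array([0, 0, 0, 1, 1])) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc(np.zeros(10), np.r_[np.zeros(5), np.ones(5)]) == 0.5

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=50)
            if y.sum() in (0, 50):
                continue
            s = np.round(rng.normal(size=50), 1)  # ties included
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_independent_scores_near_half(self, rng):
        y = np.r_[np.zeros(2000), np.ones(2000)]
        s = rng.normal(size=4000)
        assert abs(roc_auc(s, y) - 0.5) < 0.03


class TestBootstrapCI:
    def test_constant_values_zero_width(self):
        lo, hi = bootstrap_ci(np.full(10, 0.7), seed=1)
        assert lo == hi == 0.7

    def test_bernoulli_interval_brackets_half(self, rng):
        v = rng.integers(0, 2, size=400).astype(float)
        lo, hi = bootstrap_ci(v, n_boot=2000, seed=2)
        assert lo < 0.5 < hi
        assert hi - lo < 0.2

    def test_seed_determinism(self, rng):
        v = rng.normal(size=30)
        assert bootstrap_ci(v, seed=5) == bootstrap_ci(v, seed=5)
        assert bootstrap_ci(v, seed=5) != bootstrap_ci(v, seed=6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([]))


class TestCrossValidation:
    def test_separable_labels_high_accuracy(self):
        table = _synthetic_table(informative=True, n_per_class=40)
        res = cross_validate_models(table, FeatureSetModel(id=1), seed=1)
        assert res.bac_scores.shape == (5, 5)
        assert res.bac_mean > 0.95
        assert res.bac_ci95[0] <= res.bac_mean <= res.bac_ci95[1]

    def test_null_labels_near_chance(self):
        table = _synthetic_table(informative=False, n_per_class=30)
        res = cross_validate_models(table, FeatureSetModel(id=1), seed=2)
        assert 0.3 < res.bac_mean < 0.7

    def test_determinism(self):
        table = _synthetic_table()
        a = cross_validate_models(table, FeatureSetModel(id=3), seed=9)
        b = cross_validate_models(table, FeatureSetModel(id=3), seed=9)
        pd.testing.assert_frame_equal(a.bac_scores, b.bac_scores)
        pd.testing.assert_frame_equal(a.auc_scores, b.auc_scores)

    def test_feature_set_models_select_columns(self):
        assert FeatureSetModel(id=1).feature_columns == list(FIRST_ORDER_NAMES)
        assert FeatureSetModel(id=2).feature_columns == list(TEXTURE_NAMES)
        assert FeatureSetModel(id=3).feature_columns == list(FEATURE_NAMES)
        with pytest.raises(ValueError, match="robustness"):
            FeatureSetModel(id=4)

    def test_no_leakage_into_fold_standardization(self):
        """Corrupting the held-out rows of a fold must not change that
        fold's training-only standardization parameters."""
        table = _synthetic_table()
        res = cross_validate_models(table, FeatureSetModel(id=1), seed=4)
        fold0_cases = [c for c, f in res.fold_assignment.items() if f == 0]
        corrupted = table.copy()
        sel = corrupted["case_id"].isin(fold0_cases)
        corrupted.loc[sel, list(FIRST_ORDER_NAMES)] += 1e6
        res2 = cross_validate_models(corrupted, FeatureSetModel(id=1), seed=4)
        np.testing.assert_allclose(
            res.fold_scaler_means[0], res2.fold_scaler_means[0]
        )
        # but other folds (which train on those rows) do shift
        assert not np.allclose(res.fold_scaler_means[1], res2.fold_scaler_means[1])

    def test_too_few_cases_per_class(self):
        table = _synthetic_table(n_per_class=3)
        with pytest.raises(ValueError, match="at least"):
            cross_validate_models(table, FeatureSetModel(id=1), k=5, seed=0)


class TestAnovaTukey:
    def test_one_way_two_groups_equals_squared_t(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.8, 1, 25)
        df = pd.DataFrame(
            {"score": np.r_[a, b], "g": ["a"] * 25 + ["b"] * 25}
        )
        rep = factorial_anova_tukey(df, "score", ["g"])
        from scipy import stats

        t = stats.ttest_ind(a, b).statistic
        assert rep["factors"]["g"]["F"] == pytest.approx(t**2, rel=1e-9)

    def test_shifted_group_flagged_by_tukey(self, rng):
        groups = ["a", "b", "c"]
        rows = []
        for g in groups:
            shift = 5.0 if g == "c" else 0.0
            for v in rng.normal(shift, 1.0, 30):
                rows.append({"score": v, "g": g})
        rep = factorial_anova_tukey(pd.DataFrame(rows), "score", ["g"])
        assert rep["factors"]["g"]["significant"]
        flags = {
            (t["group1"], t["group2"]): t["reject"] for t in rep["factors"]["g"]["tukey"]
        }
        assert flags[("a", "c")] and flags[("b", "c")]
        assert not flags[("a", "b")]

    def test_two_way_reports_both_factors(self, rng):
        rows = []
        for f1 in ("x", "y"):
            for f2 in ("u", "v", "w"):
                shift = 2.0 if f1 == "y" else 0.0
                for v in rng.normal(shift, 1.0, 15):
                    rows.append({"score": v, "f1": f1, "f2": f2})
        rep = factorial_anova_tukey(pd.DataFrame(rows), "score", ["f1", "f2"])
        assert rep["factors"]["f1"]["significant"]
        assert not rep["factors"]["f2"]["significant"]

    def test_single_level_factor_raises(self):
        df = pd.DataFrame({"score": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            factorial_anova_tukey(df, "score", ["g"])


def test_classifier_families_complete():
    assert set(CLASSIFIER_FAMILIES) == {
        "random_forest",
        "naive_bayes",
        "logistic_regression",
        "svm",
        "neural_network",
    }
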