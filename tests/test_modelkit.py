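"""Metrics, cross-validation, learners and benchmark-table statistics."""

import numpy as np
import pandas as pd
import pytest

from toxforge import (
    EvalConfig,
    MeanLearner,
    MetricTable,
    NearestNeighborLearner,
    SklearnLearner,
    Task,
    compare_models,
    count_rows_above,
    cross_validate,
    metric_size_profile,
    rmse,
    roc_auc,
)
from toxforge.modelkit import NotFittedError


def brute_force_auc(labels, scores):
    """Independent pairwise oracle: P(positive outranks negative), ties 0.5."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = concordant = 0.0
    for p in pos:
        for n in neg:
            total += 1
            concordant += 1.0 if p > n else (0.5 if p == n else 0.0)
    return concordant / total


class TestRmse:
    def test_zero_iff_identical(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_error(self):
        assert rmse([0, 0], [1, 1]) == 1.0

    def test_single_miss_of_four(self):
        assert rmse([0, 0, 0, 0], [1, 0, 0, 0]) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_pairs_concordant(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]
        assert brute_force_auc(labels, scores) == 0.75  # oracle
        assert roc_auc(labels, scores) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
            assert roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores)
            )

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        scores = rng.normal(size=50)  # continuous → tie-free
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)


class TestLearners:
    def test_predict_before_fit_errors(self):
        for learner in (MeanLearner(), NearestNeighborLearner()):
            with pytest.raises(NotFittedError):
                learner.predict(np.zeros((2, 3)))

    def test_nearest_neighbor_memorizes_training_rows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = NearestNeighborLearner(k=1).fit(X, y)
        assert np.allclose(model.predict(X), y)

    def test_predictions_finite(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        for learner in (MeanLearner(), NearestNeighborLearner(k=3)):
            pred = learner.fit(X, y).predict(rng.normal(size=(10, 5)))
            assert np.isfinite(pred).all()

    def test_sklearn_adapter_round_trips_feature_names(self):
        from sklearn.linear_model import LinearRegression

        X = pd.DataFrame({"tpsa": [1.0, 2, 3, 4], "logp": [0.0, 1, 0, 1]})
        model = SklearnLearner(LinearRegression()).fit(X, [1.0, 2, 3, 4])
        assert model.feature_names == ["tpsa", "logp"]
        assert np.isfinite(model.predict(X)).all()


class TestCrossValidate:
    def test_constant_target_mean_learner_rmse_zero(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.full(40, 2.5)
        cv = cross_validate(X, y, MeanLearner, Task.REGRESSION, EvalConfig(seed=0))
        assert cv.mean == 0.0

    @pytest.mark.parametrize("n", [10, 53, 100])
    @pytest.mark.parametrize("k", [2, 5])
    def test_folds_partition_rows_exactly(self, n, k):
        X = np.arange(n * 2, dtype=float).reshape(n, 2)
        y = np.arange(n, dtype=float)
        cv = cross_validate(
            X, y, MeanLearner, Task.REGRESSION, EvalConfig(k_folds=k, seed=3)
        )
        all_idx = np.concatenate(cv.fold_indices)
        assert sorted(all_idx) == list(range(n))  # exhaustive and disjoint
        assert len(cv.fold_metrics) == k

    def test_same_seed_reproduces_folds_and_metrics(self):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(60, 4)), rng.normal(size=60)
        a = cross_validate(X, y, lambda: NearestNeighborLearner(3), Task.REGRESSION,
                           EvalConfig(seed=11))
        b = cross_validate(X, y, lambda: NearestNeighborLearner(3), Task.REGRESSION,
                           EvalConfig(seed=11))
        assert a.fold_metrics == b.fold_metrics
        for fa, fb in zip(a.fold_indices, b.fold_indices):
            assert np.array_equal(fa, fb)

    def test_stratified_classification_keeps_both_classes_per_fold(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = np.array([0, 1] * 25, dtype=float)
        X[y == 1] += 2.0
        cv = cross_validate(
            X, y, lambda: NearestNeighborLearner(3), Task.CLASSIFICATION,
            EvalConfig(k_folds=5, seed=0),
        )
        assert all(0.0 <= m <= 1.0 for m in cv.fold_metrics)


class TestMetricTableValidation:
    def base(self, **overrides):
        d = dict(target=["t"], task=["classification"], n_samples=[10], m=[0.9])
        d.update(overrides)
        return pd.DataFrame(d)

    def test_auc_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MetricTable(self.base(m=[1.2]))

    def test_negative_rmse_rejected(self):
        with pytest.raises(ValueError):
            MetricTable(self.base(task=["regression"], m=[-0.1]))

    def test_n_samples_at_least_one(self):
        with pytest.raises(ValueError):
            MetricTable(self.base(n_samples=[0]))


class TestCompareModels:
    def test_tox21_wins_on_shipped_table(self, paper_tables):
        _, cls = paper_tables
        tox21 = [
            t for t in cls.frame["target"]
            if t.startswith(("NR-", "SR-"))
        ]
        assert len(tox21) == 12
        result = compare_models(
            cls, "xgb_fragments", ["catboost_fp", "benchmark"], rows=tox21
        )
        assert (result.wins, result.total) == (8, 12)

    def test_overall_classification_win_percent(self, paper_tables):
        _, cls = paper_tables
        result = compare_models(cls, "xgb_fragments", ["catboost_fp", "benchmark"])
        assert result.total == 22 and result.percent == 64

    def test_single_row_win(self):
        table = MetricTable(
            pd.DataFrame(
                dict(target=["t"], task=["regression"], n_samples=[5],
                     focal=[0.4], other=[0.5])
            )
        )
        r = compare_models(table, "focal", ["other"])
        assert (r.wins, r.total, r.percent) == (1, 1, 100)

    def test_tie_is_not_a_win(self):
        table = MetricTable(
            pd.DataFrame(
                dict(target=["t"], task=["regression"], n_samples=[5],
                     focal=[0.5], other=[0.5])
            )
        )
        assert compare_models(table, "focal", ["other"]).wins == 0

    def test_empty_selection_rejected(self, paper_tables):
        _, cls = paper_tables
        with pytest.raises(ValueError):
            compare_models(cls, "xgb_fragments", ["catboost_fp"], rows=["nonesuch"])

    def test_missing_model_rejected(self, paper_tables):
        _, cls = paper_tables
        with pytest.raises(ValueError):
            compare_models(cls, "nonexistent_model", ["catboost_fp"])


class TestTableStatistics:
    def test_six_regression_datasets_exceed_ten_thousand(self, paper_tables):
        reg, _ = paper_tables
        assert count_rows_above(reg, 10_000) == 6

    def test_all_rows_counted_above_zero(self, paper_tables):
        reg, _ = paper_tables
        assert count_rows_above(reg, 0) == 29

    def test_absurd_threshold_counts_none(self, paper_tables):
        reg, _ = paper_tables
        assert count_rows_above(reg, 10**9) == 0

    def test_size_profile_sorted_with_stable_ties(self):
        table = MetricTable(
            pd.DataFrame(
                dict(
                    target=["a", "b", "c"],
                    task=["regression"] * 3,
                    n_samples=[50, 10, 10],
                    m=[0.3, 0.1, 0.2],
                )
            )
        )
        profile = metric_size_profile(table, "m")
        assert profile == [(10, 0.1), (10, 0.2), (50, 0.3)]

    def test_size_profile_length_matches_rows(self, paper_tables):
        reg, _ = paper_tables
        assert len(metric_size_profile(reg, "xgb_fragments")) == 29
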