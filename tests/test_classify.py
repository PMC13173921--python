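import numpy as np
import pandas as pd
import pytest

from oracles import auc_bruteforce
from wbtdc import (
    DeTable,
    ExpressionMatrix,
    RfGrid,
    ValidationError,
    compute_metrics,
    conventional_features,
    mann_whitney_auc,
    predict_scores,
    tune_and_fit,
)


def _separable(rng, n_per_class=30, d=2, gap=6.0):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per_class, d)),
        rng.normal(gap, 1.0, size=(n_per_class, d)),
    ])
    y = np.array(["control"] * n_per_class + ["disease"] * n_per_class)
    return pd.DataFrame(X, columns=[f"f{k}" for k in range(d)]), y


class TestTuneAndFit:
    def test_single_grid_point_selected(self, rng):
        X, y = _separable(rng)
        grid = RfGrid((1,), (2,), n_trees=50)
        model = tune_and_fit(X, y, grid, folds=3, repeats=1, seed=0)
        assert len(model.cv_table) == 1
        assert model.best_params == (1, 2)

    def test_separable_data_high_cv_accuracy(self, rng):
        X, y = _separable(rng)
        grid = RfGrid((1, 2), (2, 5), n_trees=100)
        model = tune_and_fit(X, y, grid, folds=5, repeats=1, seed=1)
        assert (model.cv_table["mean_accuracy"] >= 0.95).all()

    def test_deterministic_given_seed(self, rng):
        X, y = _separable(rng, gap=1.0)
        grid = RfGrid((1, 2), (2, 10), n_trees=50)
        a = tune_and_fit(X, y, grid, folds=3, repeats=2, seed=5)
        b = tune_and_fit(X, y, grid, folds=3, repeats=2, seed=5)
        assert a.best_params == b.best_params
        assert a.cv_table.equals(b.cv_table)

    def test_single_class_rejected(self, rng):
        X, _ = _separable(rng)
        with pytest.raises(ValidationError):
            tune_and_fit(X, np.repeat("disease", len(X)), seed=0)

    def test_folds_reduced_for_tiny_class(self, rng):
        X, y = _separable(rng, n_per_class=4)
        grid = RfGrid((1,), (2,), n_trees=20)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            tune_and_fit(X, y, grid, folds=10, repeats=1, seed=0)

    def test_stratified_folds(self, rng):
        """Per-fold class proportions stay within one sample of global."""
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = np.array([1] * 30 + [0] * 20)
        X = rng.normal(size=(50, 3))
        cv = RepeatedStratifiedKFold(n_splits=10, n_repeats=1, random_state=0)
        for _, test_idx in cv.split(X, y):
            got = y[test_idx].sum()
            expected = 30 * len(test_idx) / 50
            assert abs(got - expected) <= 1


class TestPredictScores:
    def _fitted(self, rng):
        X, y = _separable(rng)
        grid = RfGrid((1,), (2,), n_trees=100)
        return tune_and_fit(X, y, grid, folds=3, repeats=1, seed=2), X, y

    def test_saturated_model_recovers_training_labels(self, rng):
        model, X, y = self._fitted(rng)
        scores = predict_scores(model, X)
        acc = ((scores >= 0.5) == (y == "disease")).mean()
        assert acc >= 0.95

    def test_column_order_irrelevant(self, rng):
        model, X, _ = self._fitted(rng)
        shuffled = X.loc[:, list(X.columns)[::-1]]
        assert np.allclose(predict_scores(model, X), predict_scores(model, shuffled))

    def test_missing_feature_named(self, rng):
        model, X, _ = self._fitted(rng)
        with pytest.raises(ValidationError, match="f1"):
            predict_scores(model, X.drop(columns=["f1"]))

    def test_extra_columns_dropped_with_warning(self, rng):
        model, X, _ = self._fitted(rng)
        X2 = X.assign(extra=1.0)
        with pytest.warns(UserWarning, match="extra"):
            scores = predict_scores(model, X2)
        assert np.allclose(scores, predict_scores(model, X))


class TestComputeMetrics:
    def test_worked_auc_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        truth = ["disease", "disease", "control", "control"]
        rep = compute_metrics(scores, truth)
        assert rep.roc_auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        rep = compute_metrics(
            np.array([0.9, 0.8, 0.2, 0.1]),
            ["disease", "disease", "control", "control"],
        )
        assert rep.roc_auc == 1.0
        assert rep.balanced_accuracy == 1.0
        assert rep.confusion.sum() == rep.n_test == 4

    def test_constant_scores_auc_half(self):
        rep = compute_metrics(
            np.full(6, 0.5), ["disease"] * 3 + ["control"] * 3
        )
        assert rep.roc_auc == pytest.approx(0.5)

    def test_one_class_truth(self):
        with pytest.raises(ValidationError, match="single class"):
            compute_metrics(np.array([0.4, 0.6]), ["disease", "disease"])
        rep = compute_metrics(
            np.array([0.4, 0.6]), ["disease", "disease"], require_auc=False
        )
        assert rep.roc_auc is None and rep.accuracy == 0.5

    def test_balanced_accuracy_equals_accuracy_for_symmetric_errors(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])  # one error in each class
        truth = ["disease", "disease", "control", "control"]
        rep = compute_metrics(scores, truth)
        assert rep.balanced_accuracy == pytest.approx(rep.accuracy) == 0.5

    def test_auc_matches_bruteforce_pair_counting(self, rng):
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid -> ties
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                continue
            worst = max(
                worst, abs(mann_whitney_auc(scores, truth) - auc_bruteforce(scores, truth))
            )
        assert worst <= 1e-12

    def test_roc_points_monotone(self, rng):
        scores = rng.uniform(size=40)
        truth = np.where(rng.uniform(size=40) < 0.5, "disease", "control")
        rep = compute_metrics(scores, truth)
        fpr = [p[0] for p in rep.roc_points]
        tpr = [p[1] for p in rep.roc_points]
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))


class TestConventionalFeatures:
    def _setup(self, rng, n_genes=30, missing=0):
        genes = [f"g{i:02d}" for i in range(n_genes)]
        m_train = ExpressionMatrix(
            genes, [f"a{j}" for j in range(6)],
            rng.normal(size=(n_genes, 6)), "transformed",
        )
        test_genes = genes[missing:]
        m_test = ExpressionMatrix(
            test_genes, [f"b{j}" for j in range(4)],
            rng.normal(size=(len(test_genes), 4)), "log2_intensity",
        )
        half = n_genes // 2
        rows = []
        for i, g in enumerate(genes):
            fc = 2.0 - i * 0.01 if i < half else -(2.0 - (i - half) * 0.01)
            rows.append((g, fc, 0.001, 0.01, "up" if fc > 0 else "down"))
        de = DeTable(pd.DataFrame(
            rows, columns=["gene_id", "log2fc", "pvalue", "padj", "direction"]
        ))
        return m_train, m_test, de

    def test_full_feature_count(self, rng):
        m_train, m_test, de = self._setup(rng)
        tr, te = conventional_features(m_train, m_test, de, n_per_direction=10)
        assert tr.shape == (6, 20) and te.shape == (4, 20)
        assert list(tr.columns) == list(te.columns)

    def test_genes_missing_in_test_dropped_from_both(self, rng):
        m_train, m_test, de = self._setup(rng, missing=3)
        with pytest.warns(UserWarning, match="absent from the test"):
            tr, te = conventional_features(m_train, m_test, de, n_per_direction=10)
        assert tr.shape[1] == te.shape[1] == 17

    def test_single_gene_per_direction(self, rng):
        m_train, m_test, de = self._setup(rng)
        tr, te = conventional_features(m_train, m_test, de, n_per_direction=1)
        assert tr.shape[1] == 2

    def test_too_few_shared_genes_errors(self, rng):
        m_train, m_test, de = self._setup(rng, n_genes=12, missing=8)
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError, match="shared"):
                conventional_features(m_train, m_test, de, n_per_direction=4)
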