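import itertools

import numpy as np
import pandas as pd
import pytest

from transfacpred import metrics as M
from transfacpred.models import (
    FAMILIES,
    ClassifierSpec,
    cross_validate,
    grid_search,
    load_model,
    predict_score,
    save_model,
    stratified_fold_indices,
    train_classifier,
)


def separable_toy(n=60, seed=0):
    """Two features; class = sign of feature one."""
    rng = np.random.default_rng(seed)
    x1 = np.concatenate([rng.uniform(0.5, 1.5, n // 2), rng.uniform(-1.5, -0.5, n // 2)])
    x2 = rng.normal(size=n)
    X = pd.DataFrame({"f1": x1, "f2": x2})
    y = (x1 > 0).astype(int)
    return X, y


class TestTrainClassifier:
    def test_separable_data_learned_perfectly(self):
        X, y = separable_toy()
        model = train_classifier(X, y, ClassifierSpec("extra_trees", seed=1))
        pred = (predict_score(model, X) >= 0.5).astype(int)
        assert np.array_equal(pred, y)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_deterministic_for_fixed_seed(self, family):
        X, y = separable_toy(n=40)
        probe, _ = separable_toy(n=20, seed=99)
        s1 = predict_score(train_classifier(X, y, ClassifierSpec(family, seed=5)), probe)
        s2 = predict_score(train_classifier(X, y, ClassifierSpec(family, seed=5)), probe)
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        X, y = separable_toy()
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(X, np.ones_like(y), ClassifierSpec())

    def test_nan_rejected(self):
        X, y = separable_toy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_classifier(X, y, ClassifierSpec())

    def test_string_labels_accepted(self):
        X, y = separable_toy()
        labels = np.where(y == 1, "TF", "nonTF")
        model = train_classifier(X, labels, ClassifierSpec("extra_trees", seed=0))
        assert (predict_score(model, X)[y == 1] >= 0.5).all()


class TestPredictScore:
    def test_scores_within_unit_interval(self):
        X, y = separable_toy()
        model = train_classifier(X, y, ClassifierSpec("logistic_regression", seed=0))
        s = predict_score(model, X)
        assert ((0 <= s) & (s <= 1)).all()

    def test_column_mismatch_reported(self):
        X, y = separable_toy()
        model = train_classifier(X, y, ClassifierSpec())
        bad = X.rename(columns={"f2": "f3"})
        with pytest.raises(ValueError, match="f3"):
            predict_score(model, bad)

    def test_null_data_scores_near_half(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(400, 5)), columns=list("abcde"))
        y = np.tile([0, 1], 200)
        model = train_classifier(X, y, ClassifierSpec("extra_trees", seed=0))
        probe = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        assert abs(predict_score(model, probe).mean() - 0.5) < 0.1


class TestCrossValidate:
    def test_folds_partition_and_stratify(self):
        y = np.array([0] * 60 + [1] * 40)
        folds = stratified_fold_indices(y, k=5, seed=0)
        assert sorted(np.unique(folds)) == [0, 1, 2, 3, 4]
        for f in range(5):
            n_pos = np.sum((folds == f) & (y == 1))
            assert abs(n_pos - 40 / 5) <= 1
            assert np.sum(folds == f) == 20

    def test_fold_assignment_depends_only_on_seed(self):
        y = np.array([0, 1] * 30)
        assert np.array_equal(
            stratified_fold_indices(y, 5, seed=2), stratified_fold_indices(y, 5, seed=2)
        )
        assert not np.array_equal(
            stratified_fold_indices(y, 5, seed=2), stratified_fold_indices(y, 5, seed=3)
        )

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1] * 3 + [0] * 50)
        with pytest.raises(ValueError, match="at least k"):
            stratified_fold_indices(y, 5, seed=0)

    def test_mean_equals_fold_average(self):
        X, y = separable_toy(n=100, seed=3)
        cv = cross_validate(X, y, ClassifierSpec("decision_tree", seed=0), k=5, seed=0)
        assert cv.k == 5
        assert cv.mean_report.accuracy == pytest.approx(
            np.mean([r.accuracy for r in cv.fold_reports]), abs=1e-9
        )
        assert cv.mean_report.auc == pytest.approx(
            np.mean([r.auc for r in cv.fold_reports]), abs=1e-9
        )


class TestGridSearch:
    def test_single_combination_returned(self):
        X, y = separable_toy()
        best, table = grid_search(
            X, y, ClassifierSpec("decision_tree", seed=0), {"max_depth": [3]}, k=3
        )
        assert best == {"max_depth": 3}
        assert len(table) == 1

    def test_table_covers_full_product(self):
        X, y = separable_toy()
        grid = {"max_depth": [2, 4], "criterion": ["gini", "entropy"]}
        _, table = grid_search(X, y, ClassifierSpec("decision_tree", seed=0), grid, k=3)
        assert len(table) == 4

    def test_matches_independent_brute_force(self):
        X, y = separable_toy(n=60, seed=7)
        spec = ClassifierSpec("k_nearest_neighbor", seed=0)
        grid = {"n_neighbors": [1, 3, 5]}
        best, table = grid_search(X, y, spec, grid, k=3, metric="accuracy")
        # independent loop over all combinations using the same CV routine
        oracle = {}
        for (value,) in itertools.product(grid["n_neighbors"]):
            cv = cross_validate(X, y, spec.with_params(n_neighbors=value), k=3, seed=0)
            oracle[value] = cv.mean_report.accuracy
        assert best["n_neighbors"] == max(oracle, key=lambda v: oracle[v])
        assert dict(zip(table["n_neighbors"], table["mean_accuracy"])) == pytest.approx(oracle)

    def test_empty_grid_rejected(self):
        X, y = separable_toy()
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(X, y, ClassifierSpec(), {})


class TestPersistence:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        X, y = separable_toy()
        model = train_classifier(X, y, ClassifierSpec("extra_trees", seed=0))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.feature_names == model.feature_names
        assert loaded.train_fingerprint == model.train_fingerprint
        assert np.array_equal(predict_score(loaded, X), predict_score(model, X))
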