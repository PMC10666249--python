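import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from sarscape.qsar import (
    QSARModel,
    confusion_matrix,
    correlation_filter,
    cross_validate,
    metrics,
    smote_balance,
    split,
    train_ovr,
    variance_filter,
)


def gaussian_classes(rng, sizes, n_features=8, sep=3.0):
    """Linearly separated Gaussian blobs, one per class."""
    X, y = [], []
    for k, size in enumerate(sizes):
        X.append(rng.normal(loc=k * sep, scale=1.0, size=(size, n_features)))
        y += [f"class{k}"] * size
    return pd.DataFrame(np.vstack(X), columns=[f"f{i}" for i in range(n_features)]), np.array(y)


class TestFilters:
    def test_variance_filter_drops_constant_keeps_binary(self, rng):
        m = pd.DataFrame(
            {
                "const": np.ones(20),
                "binary": np.tile([0.0, 1.0], 10),  # variance ~0.26 > 0.1
                "noise": rng.normal(size=20),
            }
        )
        out, trace = variance_filter(m)
        assert trace.dropped_low_variance == ["const"]
        assert list(out.columns) == ["binary", "noise"]

    def test_variance_threshold_zero_keeps_nonconstant(self, rng):
        m = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10) * 1e-4})
        out, _ = variance_filter(m, threshold=0.0)
        assert list(out.columns) == ["a", "b"]

    def test_correlation_filter_drops_duplicate_and_negation(self, rng):
        x = rng.normal(size=30)
        m = pd.DataFrame({"x": x, "dup": x.copy(), "neg": -x, "other": rng.normal(size=30)})
        out, trace = correlation_filter(m)
        assert list(out.columns) == ["x", "other"]
        assert ("dup", "x") in trace.dropped_correlated
        assert ("neg", "x") in trace.dropped_correlated

    def test_three_mutually_correlated_keep_first(self, rng):
        x = rng.normal(size=50)
        m = pd.DataFrame(
            {
                "a": x,
                "b": x + rng.normal(scale=0.01, size=50),
                "c": x + rng.normal(scale=0.01, size=50),
            }
        )
        out, trace = correlation_filter(m)
        assert list(out.columns) == ["a"]
        assert {d for d, _ in trace.dropped_correlated} == {"b", "c"}

    def test_correlation_filter_rejects_zero_variance(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            correlation_filter(m)

    def test_filters_idempotent(self, rng):
        x = rng.normal(size=40)
        m = pd.DataFrame(
            {"a": x, "dup": x, "c": rng.normal(size=40), "const": np.full(40, 2.0)}
        )
        once, _ = variance_filter(m)
        once, _ = correlation_filter(once)
        again_v, tv = variance_filter(once)
        again_c, tc = correlation_filter(again_v)
        assert list(again_c.columns) == list(once.columns)
        assert tv.dropped_low_variance == [] and tc.dropped_correlated == []

    def test_hand_traced_ten_feature_toy(self, rng):
        """Planted constant, near-constant, duplicated and anti-correlated
        columns; the surviving set is traced by hand."""
        n = 60
        base = rng.normal(size=n)
        other = rng.normal(size=n)
        m = pd.DataFrame(
            {
                "f0_const": np.full(n, 5.0),          # var 0 -> variance filter
                "f1_tiny": rng.normal(scale=0.01, size=n),  # var ~1e-4 -> variance filter
                "f2_base": base,
                "f3_dup": base.copy(),                # r = 1 with f2 -> corr filter
                "f4_neg": -base,                      # r = -1 with f2 -> corr filter
                "f5_other": other,
                "f6_scaled": 2.5 * other + 1.0,       # r = 1 with f5 -> corr filter
                "f7_indep": rng.normal(size=n),
                "f8_noisydup": base + rng.normal(scale=0.05, size=n),  # |r| > 0.95
                "f9_indep": rng.normal(size=n),
            }
        )
        out, tv = variance_filter(m, 0.1)
        assert tv.dropped_low_variance == ["f0_const", "f1_tiny"]
        out, tc = correlation_filter(out, 0.95)
        assert list(out.columns) == ["f2_base", "f5_other", "f7_indep", "f9_indep"]
        assert {d for d, _ in tc.dropped_correlated} == {"f3_dup", "f4_neg", "f6_scaled", "f8_noisydup"}


class TestSMOTE:
    def test_published_class_counts_full_set(self, rng):
        X, y = gaussian_classes(rng, [148, 247, 154], n_features=20)
        Xb, yb = smote_balance(X, y, seed=42)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [247, 247, 247]

    def test_published_class_counts_subset(self, rng):
        X, y = gaussian_classes(rng, [24, 82, 62], n_features=20)
        _, yb = smote_balance(X, y, seed=42)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [82, 82, 82]

    def test_already_balanced_unchanged(self, rng):
        X, y = gaussian_classes(rng, [30, 30])
        Xb, yb = smote_balance(X, y)
        assert np.array_equal(Xb.to_numpy(), X.to_numpy()) and np.array_equal(yb, y)

    def test_original_rows_preserved_verbatim(self, rng):
        X, y = gaussian_classes(rng, [10, 25])
        Xb, yb = smote_balance(X, y, seed=0)
        assert np.array_equal(Xb.to_numpy()[: len(y)], X.to_numpy())
        assert np.array_equal(yb[: len(y)], y)

    def test_synthetic_rows_inside_class_hull_box(self, rng):
        X, y = gaussian_classes(rng, [8, 40])
        Xb, yb = smote_balance(X, y, seed=0)
        new = Xb.to_numpy()[len(y):]
        cls0 = X.to_numpy()[y == "class0"]
        lo, hi = cls0.min(axis=0), cls0.max(axis=0)
        # convex combinations of class members stay in the bounding box
        assert np.all(new >= lo - 1e-12) and np.all(new <= hi + 1e-12)

    def test_deterministic_per_seed(self, rng):
        X, y = gaussian_classes(rng, [12, 30])
        X1, _ = smote_balance(X, y, seed=7)
        X2, _ = smote_balance(X, y, seed=7)
        assert np.array_equal(X1.to_numpy(), X2.to_numpy())

    def test_singleton_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            smote_balance(X, ["a", "b", "b"])


class TestSplit:
    def test_ratio_80_20(self):
        labels = ["a"] * 50 + ["b"] * 50
        plan = split(list(range(100)), labels, ratio=0.8, seed=42)
        assert len(plan.train_ids) == 80 and len(plan.test_ids) == 20
        assert set(plan.train_ids) | set(plan.test_ids) == set(range(100))
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_ratio_75_25_on_168(self):
        labels = ["a"] * 24 + ["b"] * 82 + ["c"] * 62
        plan = split(list(range(168)), labels, ratio=0.75, seed=42)
        assert len(plan.train_ids) == 126 and len(plan.test_ids) == 42

    def test_reproducible(self):
        labels = ["a"] * 30 + ["b"] * 30
        p1 = split(list(range(60)), labels, seed=42)
        p2 = split(list(range(60)), labels, seed=42)
        assert p1 == p2

    def test_stratified(self):
        labels = ["a"] * 20 + ["b"] * 80
        plan = split(list(range(100)), labels, ratio=0.8, seed=1)
        train_a = sum(1 for i in plan.train_ids if i < 20)
        assert train_a == 16  # 80% of the minority class

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            split([1, 2], ["a", "b"], ratio=1.5)


class TestMetrics:
    def test_diagonal_confusion(self):
        cm = pd.DataFrame(np.diag([5, 7, 9]), index=list("abc"), columns=list("abc"))
        assert metrics(cm) == pytest.approx((1.0, 1.0, 1.0))

    def test_degenerate_single_prediction(self):
        # all predictions on one class, three balanced classes
        cm = confusion_matrix(["a"] * 10 + ["b"] * 10 + ["c"] * 10, ["a"] * 30)
        acc, rec, mcc = metrics(cm)
        assert acc == pytest.approx(1 / 3)
        assert rec == pytest.approx(1 / 3)
        assert mcc == pytest.approx(0.0)

    def test_binary_closed_form_example(self):
        cm = pd.DataFrame([[40, 10], [5, 45]], index=["pos", "neg"], columns=["pos", "neg"])
        acc, rec, mcc = metrics(cm)
        assert acc == pytest.approx(0.85)
        assert mcc == pytest.approx(0.7035, abs=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_binary_mcc_matches_closed_form(self, cells):
        tp, fn, fp_, tn = cells
        if (tp + fn) == 0 or (fp_ + tn) == 0:
            return
        cm = pd.DataFrame([[tp, fn], [fp_, tn]], index=["p", "n"], columns=["p", "n"])
        _, _, mcc = metrics(cm)
        den = np.sqrt(float((tp + fp_) * (tp + fn) * (tn + fp_) * (tn + fn)))
        expected = 0.0 if den == 0 else (tp * tn - fp_ * fn) / den
        assert mcc == pytest.approx(expected, abs=1e-10)

    def test_multiclass_mcc_matches_sklearn(self, rng):
        y_true = rng.choice(["a", "b", "c"], size=200)
        y_pred = np.where(rng.random(200) < 0.6, y_true, rng.choice(["a", "b", "c"], size=200))
        _, _, mcc = metrics(confusion_matrix(y_true, y_pred))
        assert mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics(pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"]))


class TestTrainOVR:
    def test_separable_toy_perfect_train_accuracy(self, rng):
        X, y = gaussian_classes(rng, [20, 20, 20], sep=8.0)
        clf = train_ovr(X, y, "extra_trees", seed=42, n_estimators=50)
        cm = confusion_matrix(y, clf.predict(X), classes=clf.classes)
        acc, _, _ = metrics(cm)
        assert acc == 1.0

    def test_single_class_rejected(self, rng):
        X, y = gaussian_classes(rng, [10])
        with pytest.raises(ValueError):
            train_ovr(X, y)

    def test_duplicate_rows_same_prediction(self, rng):
        X, y = gaussian_classes(rng, [15, 15], sep=6.0)
        clf = train_ovr(X, y, "extra_trees", n_estimators=50)
        pred = clf.predict(pd.concat([X.iloc[[0]], X.iloc[[0]]]))
        assert pred[0] == pred[1]

    def test_unknown_algorithm(self, rng):
        X, y = gaussian_classes(rng, [5, 5])
        with pytest.raises(ValueError, match="extra_trees"):
            train_ovr(X, y, "quantum_forest")

    @pytest.mark.parametrize("algorithm", ["random_forest", "lightgbm", "xgboost", "mlp", "gaussian_process"])
    def test_all_algorithm_families_fit_and_predict(self, algorithm, rng):
        X, y = gaussian_classes(rng, [15, 15, 15], sep=8.0)
        clf = train_ovr(X, y, algorithm, seed=42, n_estimators=30)
        acc, _, _ = metrics(confusion_matrix(y, clf.predict(X), classes=clf.classes))
        assert acc > 0.9


class TestCrossValidate:
    def test_leave_one_out_runs(self, rng):
        X, y = gaussian_classes(rng, [3, 3], sep=10.0)
        res = cross_validate(X, y, "extra_trees", k=6, seed=42, n_estimators=20)
        assert res["k"] == 3  # auto-reduced to the smallest class count
        assert len(res["folds"]) == 3

    def test_predictable_data_near_perfect(self, rng):
        X, y = gaussian_classes(rng, [25, 25], sep=10.0)
        res = cross_validate(X, y, "extra_trees", k=5, seed=42, n_estimators=30)
        assert res["accuracy"] > 0.95

    def test_shuffled_labels_give_null_mcc(self, rng):
        X, _ = gaussian_classes(rng, [40, 40], sep=6.0)
        y = np.array((["a"] * 40) + (["b"] * 40))
        y = y[rng.permutation(80)]
        res = cross_validate(X, y, "extra_trees", k=5, seed=42, n_estimators=30)
        assert abs(res["mcc"]) < 0.3  # Monte-Carlo tolerance around 0

    def test_k_too_small(self, rng):
        X, y = gaussian_classes(rng, [5, 5])
        with pytest.raises(ValueError):
            cross_validate(X, y, k=1)


class TestQSARModelPipeline:
    def _model(self, rng, **kwargs):
        X, y = gaussian_classes(rng, [30, 60, 40], n_features=10, sep=2.0)
        X["const"] = 1.0
        X["dup"] = X["f0"]
        defaults = dict(cv_folds=3, seed=42, n_estimators=30)
        defaults.update(kwargs)
        return QSARModel(matrix=X, labels=y, **defaults)

    def test_reports_and_filter_trace(self, rng):
        results = self._model(rng).fit(["extra_trees"])
        assert "const" in results.filter_trace.dropped_low_variance
        assert ("dup", "f0") in results.filter_trace.dropped_correlated
        rep = results.reports["extra_trees"]
        for block in (rep.train, rep.cv, rep.test):
            assert 0 <= block["accuracy"] <= 1
            assert -1 <= block["mcc"] <= 1
        summary = results.summary()
        assert set(summary["set"]) == {"train", "cv", "test"}

    def test_balance_then_split_reproducible_reports(self, rng):
        r1 = self._model(rng).fit(["extra_trees"])
        r2 = self._model(np.random.default_rng(1234)).fit(["extra_trees"])
        assert r1.reports["extra_trees"].to_json() == r2.reports["extra_trees"].to_json()

    def test_train_only_mode_keeps_test_untouched(self, rng):
        X, y = gaussian_classes(rng, [30, 60, 40], n_features=10, sep=2.0)
        model = QSARModel(matrix=X, labels=y, balance_mode="train_only",
                          cv_folds=3, seed=42, n_estimators=30)
        results = model.fit(["extra_trees"])
        n_test = len(results.split_plan.test_ids)
        assert n_test == 26  # 20% of 130
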