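import numpy as np
import pandas as pd
import pytest

from speechsev import model as M
from speechsev.errors import ConsistencyError, InputError, ParameterError

from conftest import random_dataset


def brute_force_spearman(true, pred):
    """Independent oracle: Pearson correlation of average ranks."""

    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rt, rp = ranks(true), ranks(pred)
    rt -= rt.mean()
    rp -= rp.mean()
    return float((rt * rp).sum() / np.sqrt((rt**2).sum() * (rp**2).sum()))


def separable_dataset(n=20, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n // 2))
    x = rng.standard_normal((n, 5)) * 0.01
    x[:, 0] = labels * 10.0
    x[:, 1] = -labels * 5.0
    x[:, 2] = labels * 2.0
    return M.LabeledDataset(
        features=pd.DataFrame(x, columns=[f"f{i}" for i in range(5)]),
        labels=labels,
        subject_ids=np.array([f"s{i}" for i in range(n)]),
    )


class TestLabeledDataset:
    def test_label_range_enforced(self):
        with pytest.raises(InputError, match="anarthria"):
            M.LabeledDataset(
                features=pd.DataFrame({"f": [1.0]}),
                labels=np.array([6]),
                subject_ids=np.array(["a"]),
            )

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            M.LabeledDataset(
                features=pd.DataFrame({"f": [1.0, 2.0]}),
                labels=np.array([1]),
                subject_ids=np.array(["a", "b"]),
            )


class TestMakeSplit:
    def test_paper_geometry_70_10_6(self):
        ds = random_dataset(n=70, seed=1)
        plan = M.make_split(ds, holdout_n=10, n_folds=6, seed=0)
        assert len(plan.holdout_ids) == 10
        assert len(plan.folds) == 6
        assert all(len(f) == 10 for f in plan.folds)
        assert len(plan.cv_ids) == 60

    def test_pure_cv(self):
        ds = random_dataset(n=24, seed=2)
        plan = M.make_split(ds, holdout_n=0, n_folds=6, seed=0)
        assert plan.holdout_ids == ()
        assert sorted(sid for f in plan.folds for sid in f) == sorted(
            set(map(str, ds.subject_ids))
        )

    def test_repeat_subject_travels_together(self):
        ds = random_dataset(n=30, seed=3)
        ids = ds.subject_ids.copy()
        ids[1] = ids[0]  # one subject with two assessments
        ds = M.LabeledDataset(ds.features, ds.labels, ids)
        plan = M.make_split(ds, holdout_n=4, n_folds=6, seed=0)
        groups = [plan.holdout_ids] + list(plan.folds)
        containing = [g for g in groups if str(ids[0]) in g]
        assert len(containing) == 1

    def test_deterministic(self):
        ds = random_dataset(n=40, seed=4)
        assert M.make_split(ds, 5, 6, seed=9) == M.make_split(ds, 5, 6, seed=9)

    def test_sizing_error(self):
        ds = random_dataset(n=7, seed=5)
        with pytest.raises(InputError):
            M.make_split(ds, holdout_n=4, n_folds=6, seed=0)

    def test_stratification_balance(self):
        # every fold should see a mix of labels when labels are plentiful
        ds = random_dataset(n=120, seed=6)
        plan = M.make_split(ds, holdout_n=0, n_folds=6, seed=1)
        label_of = dict(zip(map(str, ds.subject_ids), ds.labels))
        for fold in plan.folds:
            assert len({label_of[s] for s in fold}) >= 3


class TestTrainPredict:
    def test_separable_training_accuracy(self):
        ds = separable_dataset()
        model = M.train_gbt(ds, M.GbtParams(n_estimators=30), seed=0)
        assert M.accuracy_tol(ds.labels, M.predict(model, ds.features), 0) == 1.0

    def test_deterministic(self):
        ds = separable_dataset(seed=1)
        p1 = M.predict(M.train_gbt(ds, seed=3), ds.features)
        p2 = M.predict(M.train_gbt(ds, seed=3), ds.features)
        np.testing.assert_array_equal(p1, p2)

    def test_single_label_error(self):
        ds = separable_dataset()
        mono = M.LabeledDataset(ds.features, np.zeros_like(ds.labels), ds.subject_ids)
        with pytest.raises(InputError):
            M.train_gbt(mono)

    def test_empty_predict(self):
        ds = separable_dataset()
        model = M.train_gbt(ds, M.GbtParams(n_estimators=5), seed=0)
        assert M.predict(model, ds.features.iloc[:0]).size == 0

    def test_column_order_irrelevant(self):
        ds = separable_dataset()
        model = M.train_gbt(ds, M.GbtParams(n_estimators=10), seed=0)
        shuffled = ds.features[list(ds.features.columns[::-1])]
        np.testing.assert_array_equal(
            M.predict(model, shuffled), M.predict(model, ds.features)
        )

    def test_schema_mismatch(self):
        ds = separable_dataset()
        model = M.train_gbt(ds, M.GbtParams(n_estimators=5), seed=0)
        with pytest.raises(ConsistencyError):
            M.predict(model, ds.features.rename(columns={"f0": "zzz"}))


class TestAccuracyTol:
    def test_examples(self):
        assert M.accuracy_tol([2, 3, 1], [3, 3, 3], tol=1) == pytest.approx(2 / 3)
        assert M.accuracy_tol([1, 2], [1, 2], tol=0) == 1.0
        assert M.accuracy_tol([0, 0], [2, 2], tol=1) == 0.0

    def test_errors(self):
        with pytest.raises(InputError):
            M.accuracy_tol([], [])
        with pytest.raises(InputError):
            M.accuracy_tol([1], [1, 2])


class TestSpearman:
    def test_identical(self):
        assert M.spearman_r([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)

    def test_reversed(self):
        assert M.spearman_r([0, 1, 2, 3], [3, 2, 1, 0]) == pytest.approx(-1.0)

    def test_toy_vs_brute_force(self):
        true, pred = [0, 1, 2, 3], [1, 0, 2, 3]
        oracle = brute_force_spearman(true, pred)
        assert oracle == pytest.approx(0.8)
        assert M.spearman_r(true, pred) == pytest.approx(oracle)

    def test_ties_vs_brute_force(self):
        rng = np.random.default_rng(8)
        true = rng.integers(0, 4, 30)
        pred = rng.integers(0, 4, 30)
        assert M.spearman_r(true, pred) == pytest.approx(
            brute_force_spearman(true, pred), abs=1e-12
        )

    def test_constant_input_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(M.spearman_r([1, 1, 1], [0, 1, 2]))

    def test_too_short(self):
        with pytest.raises(InputError):
            M.spearman_r([1], [1])


class TestBootstrapCI:
    def test_perfect_predictions(self):
        true = np.arange(10) % 6
        lo, hi = M.bootstrap_ci(
            true, true, lambda t, p: M.accuracy_tol(t, p, 0), n_boot=200, seed=0
        )
        assert (lo, hi) == (1.0, 1.0)

    def test_imperfect_has_width(self):
        true = np.arange(10) % 6
        pred = true.copy()
        pred[0] = (pred[0] + 2) % 6
        lo, hi = M.bootstrap_ci(
            true, pred, lambda t, p: M.accuracy_tol(t, p, 0), n_boot=500, seed=1
        )
        assert hi > lo

    def test_n_boot_floor(self):
        with pytest.raises(ParameterError):
            M.bootstrap_ci([0, 1], [0, 1], M.accuracy_tol, n_boot=10)


class TestPermutationTest:
    def test_perfect_minimum_p(self):
        true = np.arange(60) % 6
        p, z = M.permutation_test(true, true, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)
        assert z > 2

    def test_observed_below_null_gives_one(self):
        # anti-predictions: always off by 3 -> observed tol-1 accuracy 0
        true = np.array([0, 1, 2] * 20)
        pred = (true + 3) % 6
        p, _ = M.permutation_test(true, pred, n_perm=99, seed=1)
        assert p == 1.0

    def test_n_perm_floor(self):
        with pytest.raises(ParameterError):
            M.permutation_test([0, 1], [0, 1], n_perm=10)


class TestConfusionMatrix:
    def test_diagonal(self):
        true = np.array([0, 0, 1, 3, 5])
        grid = M.confusion_matrix(true, true)
        assert grid.sum() == 5
        np.testing.assert_array_equal(np.diag(grid), [2, 1, 0, 1, 0, 1])

    def test_single_pair(self):
        grid = M.confusion_matrix([2], [4])
        assert grid[2, 4] == 1 and grid.sum() == 1

    def test_row_sums(self):
        rng = np.random.default_rng(9)
        true = rng.integers(0, 6, 50)
        pred = rng.integers(0, 6, 50)
        grid = M.confusion_matrix(true, pred)
        np.testing.assert_array_equal(grid.sum(axis=1), np.bincount(true, minlength=6))

    def test_out_of_range(self):
        with pytest.raises(InputError):
            M.confusion_matrix([6], [0])


class TestFeatureImportance:
    def test_single_informative_split(self):
        # one tree, only feature f0 informative at depth 1
        rng = np.random.default_rng(0)
        labels = np.array([0, 1] * 10)
        x = rng.standard_normal((20, 5)) * 0.01
        x[:, 0] = labels * 10.0
        ds = M.LabeledDataset(
            features=pd.DataFrame(x, columns=[f"f{i}" for i in range(5)]),
            labels=labels,
            subject_ids=np.array([f"s{i}" for i in range(20)]),
        )
        model = M.train_gbt(
            ds, M.GbtParams(n_estimators=1, max_depth=1, learning_rate=1.0), seed=0
        )
        imp = M.feature_importance([model])
        assert imp["f0"] > 0
        assert all(v == 0.0 for k, v in imp.items() if k != "f0")

    def test_unused_feature_zero(self):
        ds = separable_dataset()
        model = M.train_gbt(ds, M.GbtParams(n_estimators=10, max_depth=2), seed=0)
        imp = M.feature_importance([model])
        assert imp["f4"] == 0.0  # pure noise column at tiny scale

    def test_cross_fold_averaging(self, monkeypatch):
        ds = separable_dataset()
        m1 = M.train_gbt(ds, M.GbtParams(n_estimators=1, max_depth=1), seed=0)
        m2 = M.train_gbt(ds, M.GbtParams(n_estimators=1, max_depth=1), seed=0)
        fake = iter([[{0: 2.0}], [{0: 4.0}]])
        monkeypatch.setattr(M, "_per_tree_gains", lambda m: next(fake))
        imp = M.feature_importance([m1, m2])
        assert imp["f0"] == pytest.approx(3.0)

    def test_average_gain_per_tree_within_fold(self, monkeypatch):
        ds = separable_dataset()
        m = M.train_gbt(ds, M.GbtParams(n_estimators=1, max_depth=1), seed=0)
        # two trees use feature 0 with gains 1 and 3; one tree does not
        monkeypatch.setattr(
            M, "_per_tree_gains", lambda _: [{0: 1.0}, {0: 3.0}, {1: 7.0}]
        )
        imp = M.feature_importance([m])
        assert imp["f0"] == pytest.approx(2.0)
        assert imp["f1"] == pytest.approx(7.0)

    def test_sorted_descending(self):
        ds = separable_dataset()
        model = M.train_gbt(ds, M.GbtParams(n_estimators=10), seed=0)
        values = list(M.feature_importance([model]).values())
        assert values == sorted(values, reverse=True)

    def test_empty_error(self):
        with pytest.raises(InputError):
            M.feature_importance([])


@pytest.fixture(scope="module")
def result():
    ds = random_dataset(n=48, seed=11, informative=True)
    return M.run_experiment(
        ds,
        holdout_n=6,
        n_folds=6,
        params=M.GbtParams(n_estimators=25),
        seed=5,
        n_boot=200,
        n_perm=199,
    )


class TestRunExperiment:

    def test_structure(self, result):
        assert result.pooled_cv.accuracy <= result.pooled_cv.accuracy_tol1 <= 1.0
        assert len(result.importance) == 141
        assert result.holdout is not None
        assert result.holdout.n == 6
        assert result.pooled_cv.n == 42

    def test_confusion_marginals(self, result):
        assert result.pooled_cv.confusion.sum() == result.pooled_cv.n

    def test_informative_beats_null(self, result):
        assert result.pooled_cv.permutation_p < 0.05

    def test_id_audit(self, result):
        assert not set(result.split.holdout_ids) & set(result.split.cv_ids)

    def test_deterministic(self, result):
        ds = random_dataset(n=48, seed=11, informative=True)
        again = M.run_experiment(
            ds, holdout_n=6, n_folds=6, params=M.GbtParams(n_estimators=25),
            seed=5, n_boot=200, n_perm=199,
        )
        assert again.pooled_cv.to_dict() == result.pooled_cv.to_dict()
        assert again.holdout.to_dict() == result.holdout.to_dict()
        assert again.importance == result.importance

    def test_label_shuffle_null_behavior(self):
        # with labels shuffled, the permutation p should usually be large
        high = 0
        for rep in range(5):
            ds = random_dataset(n=36, seed=50 + rep, informative=False)
            res = M.run_experiment(
                ds, holdout_n=0, n_folds=6,
                params=M.GbtParams(n_estimators=15), seed=rep,
                n_boot=200, n_perm=199,
            )
            if res.pooled_cv.permutation_p > 0.05:
                high += 1
        assert high >= 3
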