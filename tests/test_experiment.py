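"""Repeated-holdout protocol: splitting, model ranking, feature counting."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from tnbcscm.experiment import (
    RepeatConfig,
    RepeatResult,
    count_features,
    direction_of_regulation,
    gene_count_table,
    run_experiment,
    select_best_models,
    split_train_test,
    tree_first_features,
)
from tnbcscm.metrics import MetricSet
from tnbcscm.scm import fit_scm


class TestSplit:
    def test_stratified_allocation_2_8(self):
        y = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        train, test = split_train_test(y, 0.8, seed=0)
        assert len(train) == 8 and len(test) == 2
        assert sum(np.asarray(y)[train]) == 2  # largest remainder grants the slot to the minority

    def test_even_split(self):
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        train, test = split_train_test(y, 0.5, seed=3)
        yt = np.asarray(y)[train]
        assert len(train) == 4 and yt.sum() == 2

    def test_disjoint_exhaustive_many_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(8, 60))
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() < 2:
                y[:2] = 1
            if (1 - y).sum() < 2:
                y[:2] = 0
            frac = float(rng.uniform(0.3, 0.9))
            train, test = split_train_test(y, frac, seed=trial)
            assert len(set(train) & set(test)) == 0
            assert sorted(np.concatenate([train, test]).tolist()) == list(range(n))

    def test_deterministic_per_seed(self):
        y = [1] * 5 + [0] * 25
        a = split_train_test(y, 0.8, seed=9)
        b = split_train_test(y, 0.8, seed=9)
        c = split_train_test(y, 0.8, seed=10)
        assert np.array_equal(a[0], b[0])
        assert not np.array_equal(a[0], c[0])

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test([1, 0, 0, 0], 0.8)


class TestTreeFeatures:
    def _fake_tree(self, children_left, children_right, feature):
        return SimpleNamespace(
            tree_=SimpleNamespace(
                children_left=np.asarray(children_left),
                children_right=np.asarray(children_right),
                feature=np.asarray(feature),
            )
        )

    def test_breadth_first_takes_root_proximal_splits(self):
        # root f1; depth-1 f2, f3; depth-2 f4 (must be ignored)
        tree = self._fake_tree(
            children_left=[1, 3, 5, -1, -1, -1, -1],
            children_right=[2, 4, 6, -1, -1, -1, -1],
            feature=[1, 2, 3, -2, -2, 4, -2],
        )
        attrs = [f"f{i}" for i in range(5)]
        assert tree_first_features(tree, attrs, k=3) == ["f1", "f2", "f3"]

    def test_duplicate_splits_deduplicated(self):
        tree = self._fake_tree(
            children_left=[1, 3, -1, -1, -1],
            children_right=[2, 4, -1, -1, -1],
            feature=[0, 0, -2, -2, -2],
        )
        assert tree_first_features(tree, ["a", "b"], k=3) == ["a"]

    def test_on_real_sklearn_tree(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        X = rng.normal(size=(80, 6))
        y = ((X[:, 2] > 0) & (X[:, 4] > 0)).astype(int)
        tree = DecisionTreeClassifier(random_state=0).fit(X, y)
        feats = tree_first_features(tree, [f"x{j}" for j in range(6)], k=3)
        assert 1 <= len(feats) <= 3
        assert feats[0] == f"x{tree.tree_.feature[0]}"


def _result(idx, algo, f1, acc=0.5, features=("a",)):
    m = MetricSet(accuracy=acc, precision=f1, recall=f1, f1=f1)
    return RepeatResult(idx, algo, object(), {}, m, m, list(features))


class TestSelection:
    def test_top_k_per_algorithm(self):
        results = [_result(i, "scm", f1=i / 100) for i in range(100)]
        best = select_best_models(results, k_best=10)
        assert len(best) == 10
        assert {r.repeat_index for r in best} == set(range(90, 100))

    def test_all_equal_scores_take_lowest_repeat_indices(self):
        results = [_result(i, "scm", f1=0.5) for i in range(20)]
        best = select_best_models(results, k_best=5)
        assert [r.repeat_index for r in best] == [0, 1, 2, 3, 4]

    def test_k_equals_n_is_identity(self):
        results = [_result(i, "dt", f1=i / 10) for i in range(7)]
        assert len(select_best_models(results, k_best=7)) == 7

    def test_too_few_results_rejected(self):
        with pytest.raises(ValueError, match="k_best"):
            select_best_models([_result(0, "scm", 0.5)], k_best=10)


class TestCounting:
    def _fs(self):
        from tnbcscm.views import AttributeInfo, FeatureSpace

        rng = np.random.default_rng(0)
        attrs = ["v::a", "v::b", "v::c"]
        registry = {
            "v::a": AttributeInfo("v", "a", "G1"),
            "v::b": AttributeInfo("v", "b", "G1"),
            "v::c": AttributeInfo("v", "c", "G2"),
        }
        values = rng.normal(size=(10, 3))
        values[:3, 2] += 5  # attribute c up in the positive class
        fs = FeatureSpace(
            sample_ids=[f"s{i}" for i in range(10)],
            attribute_ids=attrs,
            values=values,
            registry=registry,
        )
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        return fs, labels

    def test_each_model_counts_a_feature_once(self):
        fs, labels = self._fs()
        selected = [_result(i, "scm", 0.9, features=["v::a", "v::a"]) for i in range(10)]
        table = count_features(selected, fs, labels)
        assert table.loc[table.attribute_id == "v::a", "count"].iloc[0] == 10

    def test_gene_rollup_is_max_over_isoforms(self):
        fs, labels = self._fs()
        selected = [
            _result(i, "scm", 0.9, features=["v::a"] if i < 4 else ["v::b"])
            for i in range(11)
        ]
        table = count_features(selected, fs, labels)
        genes = gene_count_table(table)
        assert genes.loc[genes.gene_symbol == "G1", "count"].iloc[0] == 7
        assert genes.loc[genes.gene_symbol == "G1", "attribute_id"].iloc[0] == "v::b"

    def test_direction_calls(self):
        fs, labels = self._fs()
        d, m1, m0 = direction_of_regulation(fs.values[:, 2], labels)
        assert d == "up_in_tnbc" and m1 > m0
        assert direction_of_regulation(np.ones(10), labels)[0] == "unchanged"
        down = direction_of_regulation(np.array([2.0] * 3 + [5.0] * 7), labels)
        assert down[0] == "down_in_tnbc" and down[1:] == (2.0, 5.0)

    def test_direction_requires_both_classes(self):
        with pytest.raises(ValueError):
            direction_of_regulation(np.ones(4), [1, 1, 1, 1])


@pytest.fixture(scope="module")
def tiny_setup():
    from tnbcscm.cohort import CohortConfig, generate_cohort
    from tnbcscm.pipeline import build_feature_space

    cfg = CohortConfig(
        n_samples=80,
        view_widths={"isoform": 45},
        isoforms_per_gene=3,
        n_planted_down=2,
        n_planted_up=1,
        effect_size=3.0,
        seed=5,
    )
    cohort, _ = generate_cohort(cfg)
    return build_feature_space(cohort), cohort.labels


class TestRunExperiment:
    def test_result_cardinality(self, tiny_setup):
        fs, labels = tiny_setup
        rc = RepeatConfig(n_repeats=5, algorithms=("scm",), k_best=3,
                          cv_folds=3, master_seed=1)
        results = run_experiment(fs, labels, rc)
        assert len(results) == 5
        assert all(r.model_features for r in results)

    def test_same_master_seed_reproduces_f1_vector(self, tiny_setup):
        fs, labels = tiny_setup
        rc = RepeatConfig(n_repeats=4, algorithms=("scm", "dt"), k_best=2,
                          cv_folds=3, master_seed=7)
        f1 = lambda res: [r.test_metrics.f1 for r in res]
        assert f1(run_experiment(fs, labels, rc)) == f1(run_experiment(fs, labels, rc))

    def test_all_three_algorithms_produce_results(self, tiny_setup):
        fs, labels = tiny_setup
        rc = RepeatConfig(n_repeats=2, algorithms=("scm", "dt", "rf"), k_best=2,
                          cv_folds=3, rf_n_estimators=10, master_seed=2)
        results = run_experiment(fs, labels, rc)
        assert {r.algorithm for r in results} == {"scm", "dt", "rf"}
        assert len(results) == 6

    def test_no_test_leakage(self, tiny_setup):
        """Mutating held-out samples after the split never changes the model."""
        fs, labels = tiny_setup
        train, test = split_train_test(labels, 0.8, seed=3)
        Xtr, ytr = fs.values[train], labels[train]
        model = fit_scm(Xtr, ytr, 1.0, 3, attribute_ids=fs.attribute_ids)
        X_mut = fs.values.copy()
        X_mut[test] = 1e6  # corrupt every held-out sample
        model_mut = fit_scm(X_mut[train], labels[train], 1.0, 3,
                            attribute_ids=fs.attribute_ids)
        assert model.rules == model_mut.rules
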