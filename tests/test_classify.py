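"""Feature tables, tree induction and stratified cross-validation."""

import numpy as np
import pandas as pd
import pytest

from voltfp.classify import (FeatureTable, build_feature_table,
                             confusion_metrics, cross_validate, induce_tree)
from voltfp.errors import ParameterError
from voltfp.synthetic import (DatasetSpec, TISSUE_GROUPS, generate_dataset,
                              make_tissue_profiles)


def table_from(features: dict, labels) -> FeatureTable:
    frame = pd.DataFrame(features)
    frame["tissue"] = labels
    frame["subject"] = 1
    frame["replicate"] = np.arange(len(frame)) + 1
    return FeatureTable(frame, "wavelet32")


class TestFeatureTables:
    def test_wavelet_mode_keeps_all_nine_tissues(self, cleaned_dataset):
        t = build_feature_table(cleaned_dataset, "wavelet32")
        assert len(t) == 352
        assert t.features.shape[1] == 32
        assert t.labels.nunique() == 9

    def test_extremes_mode_excludes_blood_and_muscle(self, cleaned_dataset):
        t = build_feature_table(cleaned_dataset, "extremes6")
        assert len(t) == 275
        assert t.features.shape[1] == 12
        assert t.labels.nunique() == 7
        assert not set(t.labels) & {"blood", "muscle"}

    def test_minima_mode_shape(self, cleaned_dataset):
        t = build_feature_table(cleaned_dataset, "minima3")
        assert len(t) == 275
        assert t.features.shape[1] == 6
        assert not t.features.isna().any().any()

    def test_single_curve(self, cleaned_dataset):
        from voltfp.io import Dataset
        one = Dataset([next(c for c in cleaned_dataset if c.tissue == "liver")])
        t = build_feature_table(one, "minima3")
        assert t.frame.shape == (1, 9)     # 6 features + 3 labels

    def test_unknown_mode(self, cleaned_dataset):
        with pytest.raises(ParameterError, match="mode"):
            build_feature_table(cleaned_dataset, "pca")


class TestInduceTree:
    def test_perfectly_separable_gives_depth_one(self):
        x = np.r_[np.zeros(12), np.ones(12)]
        t = table_from({"f": x}, ["a"] * 12 + ["b"] * 12)
        model = induce_tree(t, minimal_leaf_size=10)
        assert model.estimator.get_depth() == 1
        assert (model.predict(t.features) == t.labels.to_numpy()).all()

    def test_every_leaf_has_min_rows(self, cleaned_dataset):
        t = build_feature_table(cleaned_dataset, "wavelet32")
        model = induce_tree(t, minimal_leaf_size=10)
        tree = model.estimator.tree_
        leaves = tree.children_left == -1
        assert tree.n_node_samples[leaves].min() >= 10

    def test_pure_table_gives_single_leaf(self):
        t = table_from({"f": np.arange(20.0)}, ["a"] * 20)
        model = induce_tree(t, 10)
        assert model.estimator.get_depth() == 0

    def test_min_leaf_one_memorises_distinct_rows(self):
        rng = np.random.default_rng(0)
        t = table_from({"f1": rng.normal(size=30), "f2": rng.normal(size=30)},
                       rng.choice(["a", "b", "c"], size=30).tolist())
        model = induce_tree(t, minimal_leaf_size=1)
        assert (model.predict(t.features) == t.labels.to_numpy()).all()

    def test_empty_table(self):
        t = table_from({"f": np.array([])}, [])
        with pytest.raises(ParameterError):
            induce_tree(t)


class TestCrossValidate:
    def test_fold_class_proportions_within_one(self, cleaned_dataset):
        from sklearn.model_selection import StratifiedKFold
        t = build_feature_table(cleaned_dataset, "wavelet32")
        y = t.labels.to_numpy()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=3)
        classes, total = np.unique(y, return_counts=True)
        for _, test in skf.split(np.zeros((len(y), 1)), y):
            counts = pd.Series(y[test]).value_counts()
            for cls, tot in zip(classes, total):
                assert abs(counts.get(cls, 0) - tot / 10) <= 1

    def test_deterministic_given_seed(self, cleaned_dataset):
        t = build_feature_table(cleaned_dataset, "wavelet32")
        a = cross_validate(t, 10, 10, seed=5)
        b = cross_validate(t, 10, 10, seed=5)
        np.testing.assert_array_equal(a.confusion, b.confusion)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_confusion_pools_all_curves(self, cleaned_dataset):
        t = build_feature_table(cleaned_dataset, "wavelet32")
        cv = cross_validate(t, 10, 10, seed=1)
        assert cv.confusion.sum() == len(t)

    def test_small_class_error_names_it(self):
        t = table_from({"f": np.arange(15.0)}, ["a"] * 12 + ["tiny"] * 3)
        with pytest.raises(ParameterError, match="tiny"):
            cross_validate(t, folds=10)


class TestConfusionMetrics:
    def test_row_precision_and_column_recall(self):
        # a predicted row with 39 correct and 1 error; a true column 37+1+2
        m = np.array([[39, 1, 0], [1, 37, 0], [0, 2, 10]])
        precision, recall, acc = confusion_metrics(m)
        assert precision[0] == pytest.approx(100 * 39 / 40)
        assert recall[1] == pytest.approx(100 * 37 / 40)
        assert acc == pytest.approx(100 * 86 / 90)

    def test_identity_matrix_is_perfect(self):
        precision, recall, acc = confusion_metrics(np.eye(4, dtype=int) * 7)
        np.testing.assert_allclose(precision, 100.0)
        np.testing.assert_allclose(recall, 100.0)
        assert acc == 100.0

    def test_empty_row_gives_nan(self):
        m = np.array([[0, 0], [3, 5]])
        precision, _, _ = confusion_metrics(m)
        assert np.isnan(precision[0])

    def test_non_square_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics(np.zeros((2, 3)))


class TestRepresentationQuality:
    def test_feature_set_ordering_on_default_preset(self, cleaned_dataset):
        """Richer representations classify no worse: minima < extremes <= wavelet."""
        accs = {}
        for mode in ("minima3", "extremes6", "wavelet32"):
            t = build_feature_table(cleaned_dataset, mode)
            accs[mode] = cross_validate(t, 10, 10, seed=0).accuracy_mean
        assert accs["minima3"] < accs["extremes6"] <= accs["wavelet32"]

    def test_tree_groups_tissues_on_grouped_preset(self):
        """Top-level splits follow the three designed tissue clusters."""
        profs = make_tissue_profiles(1, preset="grouped")
        ds = generate_dataset(DatasetSpec(seed=1), profs)
        t = build_feature_table(ds, "wavelet32")
        model = induce_tree(t, 10)
        tree = model.estimator.tree_
        x = t.features.to_numpy()
        y = t.labels.to_numpy()

        def node_at_depth(depth):
            node = np.zeros(len(x), dtype=int)
            for _ in range(depth):
                nxt = node.copy()
                for i, n in enumerate(node):
                    if tree.children_left[n] == -1:
                        continue
                    go_left = x[i, tree.feature[n]] <= tree.threshold[n]
                    nxt[i] = tree.children_left[n] if go_left else tree.children_right[n]
                node = nxt
            return node

        d1, d2 = node_at_depth(1), node_at_depth(2)
        maj1 = {c: np.bincount(d1[y == c]).argmax() for c in np.unique(y)}
        maj2 = {c: np.bincount(d2[y == c]).argmax() for c in np.unique(y)}
        for group in TISSUE_GROUPS:
            assert len({maj1[c] for c in group}) == 1   # group not split at root
        sets2 = [{maj2[c] for c in group} for group in TISSUE_GROUPS]
        for i in range(len(sets2)):
            for j in range(i + 1, len(sets2)):
                assert sets2[i].isdisjoint(sets2[j])    # groups apart by depth 2
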