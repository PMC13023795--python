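import numpy as np
import pandas as pd
import pytest

import ecgmi
from ecgmi.classify import ConfusionCounts, cross_validate


def _blobs(n_per_class=60, n_features=8, sep=10.0, seed=0):
    """Perfectly separated two-cluster data labeled MI / healthy."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2 * n_per_class, n_features))
    x[n_per_class:] += sep
    y = np.array(["healthy"] * n_per_class + ["MI"] * n_per_class)
    perm = rng.permutation(y.size)
    return x[perm], y[perm]


class TestFolds:
    def test_equal_fold_sizes(self):
        y = np.array(["MI"] * 50 + ["healthy"] * 50)
        fold = ecgmi.make_folds(y, k=10, seed=1)
        assert np.all(np.bincount(fold) == 10)

    def test_every_sample_in_exactly_one_test_fold(self):
        y = np.array(["MI"] * 37 + ["healthy"] * 23)
        fold = ecgmi.make_folds(y, k=5, seed=2)
        assert fold.size == 60 and set(fold) == set(range(5))

    def test_stratification_within_one(self):
        y = np.array(["MI"] * 60 + ["healthy"] * 40)
        fold = ecgmi.make_folds(y, k=10, seed=3)
        for f in range(10):
            labels = y[fold == f]
            assert abs((labels == "MI").sum() - 6) <= 1
            assert abs((labels == "healthy").sum() - 4) <= 1

    def test_class_smaller_than_k_rejected(self):
        y = np.array(["MI"] * 5 + ["healthy"] * 50)
        with pytest.raises(ValueError, match="MI"):
            ecgmi.make_folds(y, k=10)


class TestTrainPredict:
    @pytest.mark.parametrize("cid", ecgmi.CLASSIFIER_IDS)
    def test_separable_clusters_classified_perfectly(self, cid):
        x, y = _blobs()
        pred = ecgmi.train_predict(cid, x[:80], y[:80], x[80:], seed=0)
        assert np.array_equal(pred, y[80:])

    def test_single_class_train_rejected(self):
        x = np.zeros((10, 3))
        with pytest.raises(ValueError):
            ecgmi.train_predict("kNN", x, np.array(["MI"] * 10), x)

    def test_knn_memorizes_training_set(self):
        x, y = _blobs(n_per_class=30, sep=3.0)
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        clf = Pipeline([("s", StandardScaler()),
                        ("k", KNeighborsClassifier(n_neighbors=1))])
        clf.fit(x, y)
        assert np.array_equal(clf.predict(x), y)


class TestMetrics:
    def test_worked_arithmetic(self):
        rep = ecgmi.compute_metrics(ConfusionCounts(tp=90, fp=10, tn=40, fn=10))
        assert round(rep.acc, 1) == 86.7
        assert round(rep.rec, 1) == 90.0
        assert round(rep.spe, 1) == 80.0
        assert round(rep.ppv, 1) == 90.0
        assert round(rep.npv, 1) == 80.0

    def test_perfect_counts_give_all_hundred(self):
        rep = ecgmi.compute_metrics(ConfusionCounts(tp=10, fp=0, tn=5, fn=0))
        assert (rep.acc, rep.rec, rep.spe, rep.ppv, rep.npv) == (100.0,) * 5

    def test_zero_denominator_flags_missing(self):
        rep = ecgmi.compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(rep.ppv)
        assert rep.acc == 50.0 and rep.spe == 100.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ecgmi.compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestCrossValidation:
    def test_pooled_accuracy_equals_weighted_fold_mean(self):
        x, y = _blobs(n_per_class=55, sep=1.0, seed=5)  # overlapping clusters
        fold = ecgmi.make_folds(y, k=10, seed=5)
        rep = cross_validate("kNN", x, y, fold, seed=5)
        fold_accs = [(c.tp + c.tn, c.total) for c in rep.fold_counts]
        weighted = 100.0 * sum(a for a, _ in fold_accs) / sum(t for _, t in fold_accs)
        assert abs(weighted - rep.acc) < 1e-12
        assert sum(c.total for c in rep.fold_counts) == y.size

    def test_standardization_uses_train_fold_statistics_only(self):
        x, y = _blobs(n_per_class=20, seed=6)
        fold = ecgmi.make_folds(y, k=4, seed=6)
        _, models = cross_validate("SVM", x, y, fold, seed=6, return_models=True)
        for f, model in enumerate(models):
            train_mean = x[fold != f].mean(axis=0)
            assert np.allclose(model.named_steps["scale"].mean_, train_mean)
            assert not np.allclose(model.named_steps["scale"].mean_, x.mean(axis=0))

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(200, 20))
        accs = []
        for s in range(3):
            y = np.array(["MI", "healthy"] * 100)
            y = y[np.random.default_rng(s).permutation(200)]
            fold = ecgmi.make_folds(y, k=10, seed=s)
            accs.append(cross_validate("kNN", x, y, fold, seed=s).acc)
        assert abs(np.mean(accs) - 50.0) < 5.0


class TestRunExperiment:
    def test_grid_shape_and_determinism(self):
        x, y = _blobs(n_per_class=30, seed=9)
        cols = [f"orj_f{i}" for i in range(4)] + [f"d1_f{i}" for i in range(4)]
        df = pd.DataFrame(x, columns=cols)
        df["label"] = y
        subsets = {"orj": cols[:4], "d1": cols[4:], "all": cols}
        reports = ecgmi.run_experiment(df, ("BT", "kNN"), subsets, k=5, seed=4)
        assert len(reports) == 6
        assert {(r.feature_set, r.classifier_id) for r in reports} == {
            (s, c) for s in subsets for c in ("BT", "kNN")}
        reports2 = ecgmi.run_experiment(df, ("BT", "kNN"), subsets, k=5, seed=4)
        for a, b in zip(reports, reports2):
            assert a.as_dict() == b.as_dict()
        grid = ecgmi.accuracy_table(reports)
        assert set(grid.columns) >= {"feature_set", "n_features", "BT", "kNN"}

    def test_rows_with_missing_features_dropped_per_subset(self):
        x, y = _blobs(n_per_class=30, seed=10)
        df = pd.DataFrame(x[:, :4], columns=[f"orj_f{i}" for i in range(4)])
        df["label"] = y
        df.loc[0, "orj_f0"] = np.nan
        reports = ecgmi.run_experiment(df, ("kNN",), {"all": list(df.columns[:4])},
                                       k=5, seed=1)
        assert reports[0].counts.total == 59
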