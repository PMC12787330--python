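import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier

from gearvoc import (
    FeatureTable,
    SplitSpec,
    build_feature_table,
    evaluate,
    fit_kernel_nb,
    fit_subspace_discriminant,
    fit_subspace_knn,
    preprocess_recording,
    shapley_importance,
    split,
    subset_sensors,
)
from gearvoc.data import CHANNEL_NAMES

from conftest import clean_config
from gearvoc.synthetic import synthesize_dataset


def blob_table(n_per_class=200, n_classes=4, p=8, sep=6.0, seed=0):
    """Well-separated Gaussian blobs: class means ``sep`` sds apart."""
    rng = np.random.default_rng(seed)
    means = rng.normal(scale=sep, size=(n_classes, p))
    rows, labels = [], []
    for c in range(n_classes):
        rows.append(means[c] + rng.normal(size=(n_per_class, p)))
        labels += [f"class{c}"] * n_per_class
    return FeatureTable(
        features=np.vstack(rows),
        labels=np.array(labels),
        feature_names=[f"f{j}" for j in range(p)],
        group_ids=np.arange(n_per_class * n_classes).astype(str),
    )


@pytest.fixture(scope="module")
def gear_table():
    cfg = clean_config(n_time=60, noise_sd=0.02)
    recordings, _ = synthesize_dataset(cfg)
    return build_feature_table([preprocess_recording(r) for r in recordings])


class TestFeatureTable:
    def test_build_pools_all_readings(self, gear_table):
        # 8 gears x 2 replicates x 60 instances
        assert gear_table.features.shape == (8 * 2 * 60, 35)
        assert gear_table.feature_names == CHANNEL_NAMES
        assert set(gear_table.labels) == {
            g for g in np.unique(gear_table.labels)
        }

    def test_labels_preserve_gear_spelling(self, gear_table):
        assert "Gillnet (two panels)" in set(gear_table.labels)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_feature_table([])

    def test_subset_ladder_sizes(self, gear_table):
        assert subset_sensors(gear_table, ["MQ-4", "MQ-7"]).features.shape[1] == 10
        assert subset_sensors(
            gear_table, ["MQ2", "MQ3", "MQ4", "MQ5", "MQ6", "MQ7", "MQ8"]
        ).features.shape[1] == 35

    def test_subset_errors(self, gear_table):
        with pytest.raises(ValueError):
            subset_sensors(gear_table, [])
        with pytest.raises(KeyError, match="MQ9"):
            subset_sensors(gear_table, ["MQ9"])


class TestSplit:
    def test_exact_sizes_on_balanced_classes(self):
        n_per = 2600
        table = FeatureTable(
            features=np.zeros((8 * n_per, 2)),
            labels=np.repeat([f"g{i}" for i in range(8)], n_per),
            feature_names=["a", "b"],
            group_ids=np.zeros(8 * n_per).astype(str),
        )
        train, val, test = split(table, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (13520, 5200, 2080)

    def test_deterministic_per_seed(self, gear_table):
        s1 = split(gear_table, SplitSpec(seed=5))
        s2 = split(gear_table, SplitSpec(seed=5))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.features, b.features)

    def test_stratification_keeps_every_class(self, gear_table):
        train, val, test = split(gear_table, SplitSpec(seed=1))
        classes = set(gear_table.labels)
        for part in (train, val, test):
            assert set(part.labels) == classes

    def test_grouped_split_keeps_recordings_whole(self):
        cfg = clean_config(n_time=40, n_replicates=4, noise_sd=0.02)
        recordings, _ = synthesize_dataset(cfg)
        table = build_feature_table([preprocess_recording(r) for r in recordings])
        train, val, test = split(
            table, SplitSpec(0.5, 0.25, 0.25, seed=0, grouped=True)
        )
        for a, b in ((train, val), (train, test), (val, test)):
            assert set(a.group_ids).isdisjoint(set(b.group_ids))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.5, 0.5)


class TestSubspaceKNN:
    def test_degenerate_ensemble_equals_plain_knn(self):
        table = blob_table(n_per_class=60, sep=2.0)
        model = fit_subspace_knn(
            table, n_learners=1, subspace_dim=8, k_neighbors=1, seed=0
        )
        rng = np.random.default_rng(1)
        query = rng.normal(scale=4.0, size=(100, 8))
        sk = KNeighborsClassifier(n_neighbors=1).fit(table.features, table.labels)
        np.testing.assert_array_equal(model.predict(query), sk.predict(query))

    def test_separable_blobs_high_accuracy(self):
        table = blob_table(n_per_class=200, n_classes=4, sep=6.0)
        train, val, test = split(table, SplitSpec(seed=0))
        model = fit_subspace_knn(train, seed=0)
        report = evaluate(model, val, test)
        assert report.accuracy_val >= 95.0 and report.accuracy_test >= 95.0

    def test_deterministic_per_seed(self):
        table = blob_table(n_per_class=40)
        m1 = fit_subspace_knn(table, seed=3)
        m2 = fit_subspace_knn(table, seed=3)
        assert all(
            np.array_equal(a, b) for a, b in zip(m1.subspaces_, m2.subspaces_)
        )
        x = np.random.default_rng(0).normal(size=(20, 8))
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))

    def test_degenerate_sizes_rejected(self):
        table = blob_table(n_per_class=5)
        with pytest.raises(ValueError):
            fit_subspace_knn(table, subspace_dim=99)
        with pytest.raises(ValueError):
            fit_subspace_knn(table, k_neighbors=10**6)


class TestKernelNaiveBayes:
    def test_boundary_between_separated_classes(self):
        x = np.concatenate([np.random.default_rng(0).normal(-4, 1, 100),
                            np.random.default_rng(1).normal(4, 1, 100)])
        table = FeatureTable(
            features=x[:, None],
            labels=np.array(["lo"] * 100 + ["hi"] * 100),
            feature_names=["f"],
            group_ids=np.zeros(200).astype(str),
        )
        model = fit_kernel_nb(table)
        assert model.predict(np.array([[-2.0]]))[0] == "lo"
        assert model.predict(np.array([[2.0]]))[0] == "hi"
        # prediction flips exactly once along the axis (symmetric design)
        grid = np.linspace(-6, 6, 200)[:, None]
        pred = model.predict(grid)
        assert np.sum(pred[1:] != pred[:-1]) == 1

    def test_duplicated_feature_squares_its_density_term(self):
        """Naive independence made visible: duplicating a feature adds its
        log-density a second time, i.e. the duplicated model's log-posterior
        equals the original plus the single-feature contribution."""
        table = blob_table(n_per_class=50, p=3, sep=6.0)
        model = fit_kernel_nb(table)
        dup = FeatureTable(
            features=np.hstack([table.features, table.features[:, [0]]]),
            labels=table.labels,
            feature_names=table.feature_names + ["f0_copy"],
            group_ids=table.group_ids,
        )
        model_dup = fit_kernel_nb(dup)
        solo = fit_kernel_nb(
            FeatureTable(
                features=table.features[:, [0]],
                labels=table.labels,
                feature_names=["f0"],
                group_ids=table.group_ids,
            )
        )
        lp = model._log_posteriors(table.features)
        lp_dup = model_dup._log_posteriors(dup.features)
        lp_solo = solo._log_posteriors(table.features[:, [0]])
        np.testing.assert_allclose(
            lp_dup, lp + (lp_solo - solo.log_priors_), atol=1e-9
        )

    def test_zero_variance_feature_floors_bandwidth(self):
        rng = np.random.default_rng(3)
        features = np.hstack([rng.normal(size=(40, 1)), np.ones((40, 1))])
        features[20:, 1] = 2.0  # constant within each class
        table = FeatureTable(
            features=features,
            labels=np.array(["a"] * 20 + ["b"] * 20),
            feature_names=["f0", "f1"],
            group_ids=np.zeros(40).astype(str),
        )
        model = fit_kernel_nb(table)
        assert np.all(model.bandwidths_ > 0)

    def test_minimum_class_size_enforced(self):
        table = FeatureTable(
            features=np.zeros((3, 1)),
            labels=np.array(["a", "a", "b"]),
            feature_names=["f"],
            group_ids=np.zeros(3).astype(str),
        )
        with pytest.raises(ValueError):
            fit_kernel_nb(table)


class TestSubspaceDiscriminant:
    def test_degenerate_ensemble_equals_plain_lda(self):
        table = blob_table(n_per_class=80, sep=3.0)
        model = fit_subspace_discriminant(table, n_learners=1, subspace_dim=8, seed=0)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(
            table.features, table.labels
        )
        query = np.random.default_rng(4).normal(scale=3.0, size=(200, 8))
        agree = np.mean(model.predict(query) == sk.predict(query))
        assert agree >= 0.98  # identical up to the tiny shrinkage ridge

    def test_linearly_separable_training_accuracy(self):
        table = blob_table(n_per_class=100, n_classes=2, sep=8.0)
        model = fit_subspace_discriminant(table, seed=0)
        assert np.mean(model.predict(table.features) == table.labels) == 1.0

    def test_deterministic_per_seed(self):
        table = blob_table(n_per_class=40)
        m1 = fit_subspace_discriminant(table, seed=2)
        m2 = fit_subspace_discriminant(table, seed=2)
        x = np.random.default_rng(5).normal(size=(30, 8))
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))


class _StubModel:
    """Minimal classifier protocol for evaluation edge cases."""

    def __init__(self, classes, feature_names, proba_fn):
        self.classes_ = np.asarray(classes)
        self.feature_names = feature_names
        self._fn = proba_fn

    def predict_proba(self, x):
        return self._fn(np.atleast_2d(x))

    def predict(self, x):
        return self.classes_[np.argmax(self.predict_proba(x), axis=1)]


class TestEvaluate:
    @staticmethod
    def balanced_table(n_classes=8, n_per=30):
        rng = np.random.default_rng(0)
        return FeatureTable(
            features=rng.normal(size=(n_classes * n_per, 2)),
            labels=np.repeat([f"g{i}" for i in range(n_classes)], n_per),
            feature_names=["a", "b"],
            group_ids=np.zeros(n_classes * n_per).astype(str),
        )

    def test_constant_predictor_on_balanced_8_classes(self):
        table = self.balanced_table()
        stub = _StubModel(
            [f"g{i}" for i in range(8)], ["a", "b"],
            lambda x: np.tile(np.eye(8)[0], (x.shape[0], 1)),
        )
        report = evaluate(stub, table, table)
        assert report.accuracy_val == pytest.approx(12.5)
        assert report.confusion_val[:, 0].sum() == len(table)

    def test_accuracy_equals_confusion_trace(self):
        table = blob_table(n_per_class=60)
        train, val, test = split(table, SplitSpec(seed=0))
        report = evaluate(fit_subspace_knn(train, seed=0), val, test)
        assert report.accuracy_val == pytest.approx(
            100.0 * np.trace(report.confusion_val) / len(val)
        )
        assert report.confusion_test.sum() == len(test)

    def test_feature_name_mismatch_rejected(self):
        table = self.balanced_table()
        stub = _StubModel(["g0"], ["x", "y"], lambda x: np.ones((x.shape[0], 1)))
        with pytest.raises(ValueError):
            evaluate(stub, table, table)

    def test_unknown_label_rejected(self):
        table = self.balanced_table(n_classes=2)
        stub = _StubModel(["g0"], ["a", "b"], lambda x: np.ones((x.shape[0], 1)))
        with pytest.raises(ValueError):
            evaluate(stub, table, table)


class TestShapley:
    @staticmethod
    def additive_model(coeffs, background):
        """Two-'class' scoring model with an additive score function."""
        coeffs = np.asarray(coeffs)

        def proba(x):
            score = 1.0 / (1.0 + np.exp(-(x @ coeffs) / 4.0))
            return np.column_stack([score, 1 - score])

        return _StubModel(["pos", "neg"], [f"f{j}" for j in range(len(coeffs))], proba)

    @staticmethod
    def exact_shapley(model, x, background, target):
        """Brute-force coalition enumeration with background marginalization."""
        p = x.shape[1]
        from itertools import combinations
        from math import factorial

        phi = np.zeros((x.shape[0], p))
        for j in range(p):
            others = [k for k in range(p) if k != j]
            for size in range(p):
                for subset in combinations(others, size):
                    weight = (
                        factorial(len(subset)) * factorial(p - len(subset) - 1)
                        / factorial(p)
                    )
                    for with_j in (False, True):
                        cols = list(subset) + ([j] if with_j else [])
                        vals = []
                        for z in background:
                            w = np.tile(z, (x.shape[0], 1))
                            w[:, cols] = x[:, cols]
                            vals.append(
                                model.predict_proba(w)[np.arange(x.shape[0]), target]
                            )
                        v = np.mean(vals, axis=0)
                        phi[:, j] += weight * v if with_j else -weight * v
        return phi

    def test_monte_carlo_matches_enumeration_on_additive_model(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(6, 3))
        background = rng.normal(size=(8, 3))
        model = self.additive_model([1.5, -2.0, 0.8], background)
        table = FeatureTable(
            features=np.vstack([x, background]),
            labels=np.array(["pos"] * 14),
            feature_names=model.feature_names,
            group_ids=np.zeros(14).astype(str),
        )
        est = shapley_importance(model, table, n_samples=2000, seed=0,
                                 background_size=14)
        target = np.array(
            [np.argmax(p) for p in model.predict_proba(table.features)]
        )
        exact = self.exact_shapley(model, table.features, table.features, target)
        exact_importance = np.abs(exact).mean(axis=0)
        np.testing.assert_allclose(est, exact_importance, rtol=0.05)

    def test_constant_feature_scores_near_zero(self):
        rng = np.random.default_rng(7)
        features = np.hstack([rng.normal(size=(40, 2)), np.full((40, 1), 3.0)])
        model = self.additive_model([1.0, -1.0, 2.0], features)
        table = FeatureTable(
            features=features,
            labels=np.array(["pos"] * 40),
            feature_names=model.feature_names,
            group_ids=np.zeros(40).astype(str),
        )
        imp = shapley_importance(model, table, n_samples=100, seed=1)
        assert imp[2] < 0.02
        assert imp[2] < 0.2 * max(imp[0], imp[1])

    def test_importance_invariant_to_column_order(self):
        rng = np.random.default_rng(8)
        features = rng.normal(size=(30, 3))
        model = self.additive_model([1.0, -0.5, 2.0], features)
        table = FeatureTable(
            features=features,
            labels=np.array(["pos"] * 30),
            feature_names=model.feature_names,
            group_ids=np.zeros(30).astype(str),
        )
        imp = shapley_importance(model, table, n_samples=400, seed=2)
        perm = [2, 0, 1]
        model_p = self.additive_model(np.array([1.0, -0.5, 2.0])[perm], features[:, perm])
        table_p = FeatureTable(
            features=features[:, perm],
            labels=table.labels,
            feature_names=[f"f{j}" for j in range(3)],
            group_ids=table.group_ids,
        )
        imp_p = shapley_importance(model_p, table_p, n_samples=400, seed=9)
        np.testing.assert_allclose(imp_p, imp[perm], rtol=0.15, atol=0.01)
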