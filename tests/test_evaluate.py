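"""Evaluation harness: AUC, classifiers, repeated holdout, SHAP, Wilcoxon."""

import numpy as np
import pytest

from vowelpd.errors import DegenerateInputError
from vowelpd.evaluate import (
    EvalResult,
    FeatureDataset,
    ImageDataset,
    ModelSpec,
    StepwiseLogit,
    auc,
    compare_auc_distributions,
    fit_cnn_head,
    fit_random_forest,
    repeated_holdout,
    shap_importance,
)


def _feature_ds(X, y):
    n, p = X.shape
    return FeatureDataset(
        X=X, y=y,
        subject_ids=tuple(f"s{i}" for i in range(n)),
        feature_names=tuple(f"f{j}" for j in range(p)),
    )


def _separable_images(n_per_class=15, seed=0, size=128):
    """Images whose bright horizontal band position encodes the class."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([1] * n_per_class + [0] * n_per_class)
    imgs = np.zeros((n, size, size, 3))
    for i in range(n):
        imgs[i] += rng.uniform(0.15, 0.35)
        row = 40 if y[i] else 80
        imgs[i, row : row + 8] += 0.4
        imgs[i] += 0.05 * rng.standard_normal((size, size, 3))
    return ImageDataset(np.clip(imgs, 0, 1), y,
                        tuple(f"s{i}" for i in range(n)))


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_half(self):
        assert auc(np.ones(8), np.array([1, 1, 1, 1, 0, 0, 0, 0])) == 0.5

    def test_concordant_pair_count(self):
        # positives 0.9, 0.3 vs negatives 0.8, 0.2: 3 of 4 pairs concordant
        scores = np.array([0.9, 0.3, 0.8, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auc(scores, labels) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        base = auc(scores, labels)
        assert auc(np.exp(5 * scores), labels) == pytest.approx(base)
        assert auc(np.log(scores + 1e-9), labels) == pytest.approx(base)


class TestRandomForest:
    def test_planted_feature_ranks_first(self):
        """A label-aligned feature wins the Gini ranking run after run."""
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(trial)
            y = np.array([1] * 30 + [0] * 30)
            X = rng.standard_normal((60, 33))
            X[:, 7] = y + 0.1 * rng.standard_normal(60)
            _, gini = fit_random_forest(_feature_ds(X, y), seed=trial)
            hits += gini.values.index[0] == "f7"
        assert hits >= 19

    def test_training_auc_on_separable_data(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 20 + [0] * 20)
        X = rng.standard_normal((40, 5))
        X[:, 0] = 3.0 * y + 0.1 * rng.standard_normal(40)
        model, _ = fit_random_forest(_feature_ds(X, y), seed=0)
        assert auc(model.predict_proba(X)[:, 1], y) >= 0.99

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            fit_random_forest(_feature_ds(X, np.ones(20, dtype=int)))


class TestStepwiseLogit:
    def test_planted_feature_selected(self):
        hits = 0
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            y = np.array([1] * 30 + [0] * 30)
            X = rng.standard_normal((60, 10))
            X[:, 3] = y + 0.5 * rng.standard_normal(60)
            model = StepwiseLogit().fit(X, y)
            hits += 3 in model.selected
        assert hits >= 9

    def test_null_features_select_few(self):
        sizes = []
        for trial in range(10):
            rng = np.random.default_rng(200 + trial)
            y = np.array([1] * 25 + [0] * 25)
            X = rng.standard_normal((50, 15))
            sizes.append(len(StepwiseLogit().fit(X, y).selected))
        assert np.mean(sizes) <= 2.0

    def test_minimum_rows_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            StepwiseLogit().fit(rng.standard_normal((10, 3)),
                                np.array([1, 0] * 5))

    def test_separable_data_flagged_not_crashed(self):
        y = np.array([1] * 10 + [0] * 10)
        X = np.column_stack([y * 10.0, np.arange(20.0)])
        model = StepwiseLogit().fit(X, y)
        probs = model.predict_proba(X)
        assert np.all((probs >= 0) & (probs <= 1))
        assert auc(probs[:, 1], y) == 1.0


class TestCNNHead:
    def test_separable_images_learned(self):
        ds = _separable_images(seed=5)
        train = np.concatenate([np.arange(0, 10), np.arange(15, 25)])
        test = np.concatenate([np.arange(10, 15), np.arange(25, 30)])
        model = fit_cnn_head(
            ImageDataset(ds.images[train], ds.y[train],
                         tuple(ds.subject_ids[i] for i in train)),
            seed=1,
        )
        scores = model.predict_proba(ds.images[test])[:, 1]
        assert auc(scores, ds.y[test]) >= 0.8

    def test_training_loss_decreases_and_val_tracks(self):
        ds = _separable_images(seed=6)
        train = np.concatenate([np.arange(0, 10), np.arange(15, 25)])
        val = np.concatenate([np.arange(10, 15), np.arange(25, 30)])
        model = fit_cnn_head(
            ImageDataset(ds.images[train], ds.y[train],
                         tuple(ds.subject_ids[i] for i in train)),
            seed=2,
            val=ImageDataset(ds.images[val], ds.y[val],
                             tuple(ds.subject_ids[i] for i in val)),
        )
        curve = model.curve
        assert len(curve.train_loss) == 10
        assert curve.train_loss[-1] < curve.train_loss[0]
        assert len(curve.val_loss) == 10
        assert curve.val_loss[-1] < curve.val_loss[0] + 0.1  # tracks training

    def test_permuted_labels_near_chance(self):
        ds = _separable_images(seed=7)
        rng = np.random.default_rng(0)
        aucs = []
        for it in range(4):
            yp = rng.permutation(ds.y)
            dsp = ImageDataset(ds.images, yp, ds.subject_ids)
            res = repeated_holdout(dsp, ModelSpec(kind="cnn_head"),
                                   n_iter=2, seed=it)
            aucs.extend(res.aucs)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_single_class_rejected(self):
        ds = _separable_images(seed=8)
        with pytest.raises(ValueError):
            fit_cnn_head(
                ImageDataset(ds.images[:10], np.ones(10, dtype=int),
                             tuple(ds.subject_ids[:10])),
            )


class TestRepeatedHoldout:
    def _quick_ds(self, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * 25 + [0] * 25)
        X = rng.standard_normal((50, 8))
        X[:, 0] = y + 0.4 * rng.standard_normal(50)
        return _feature_ds(X, y)

    def test_hundred_iterations_produce_hundred_aucs(self):
        ds = self._quick_ds()
        spec = ModelSpec(kind="random_forest", n_trees=30)
        res = repeated_holdout(ds, spec, n_iter=100, seed=1)
        assert len(res.aucs) == 100
        assert np.all((res.aucs >= 0.0) & (res.aucs <= 1.0))

    def test_same_seed_identical_sequence(self):
        ds = self._quick_ds()
        spec = ModelSpec(kind="random_forest", n_trees=30)
        a = repeated_holdout(ds, spec, n_iter=8, seed=9)
        b = repeated_holdout(ds, spec, n_iter=8, seed=9)
        assert np.array_equal(a.aucs, b.aucs)

    def test_subject_level_split_disjoint(self):
        """No subject appears in both sides of any split."""
        from vowelpd.evaluate import _subject_split

        rng = np.random.default_rng(4)
        for _ in range(50):
            tr, te = _subject_split(37, 0.7, rng)
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 37

    def test_permutation_null_feature_model(self):
        ds = self._quick_ds(seed=3)
        rng = np.random.default_rng(0)
        dsp = _feature_ds(ds.X, rng.permutation(ds.y))
        spec = ModelSpec(kind="random_forest", n_trees=100)
        res = repeated_holdout(dsp, spec, n_iter=20, seed=2)
        assert 0.4 <= res.aucs.mean() <= 0.6


class TestShapImportance:
    class _Additive:
        def predict_proba(self, X):
            p = 1.0 / (1.0 + np.exp(-(2.0 * X[:, 0] + 1.0 * X[:, 1])))
            return np.column_stack([1 - p, p])

    def test_ignored_feature_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3))
        table = shap_importance(self._Additive(), X, ("a", "b", "c"),
                                n_samples=150, seed=1)
        assert table.values["c"] < 0.01

    def test_attribution_tracks_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 2)) * 0.5
        table = shap_importance(self._Additive(), X, ("a", "b"),
                                n_samples=400, seed=2)
        ratio = table.values["a"] / table.values["b"]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_efficiency_sums_telescope(self):
        """Per-draw contributions sum to f(x) - f(background)."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 3))
        model = self._Additive()
        # with the full dataset as background, total attribution equals
        # mean(f(x) - f(z)) up to Monte-Carlo error in z draws
        table = shap_importance(model, X, ("a", "b", "c"),
                                n_samples=500, seed=3)
        f = model.predict_proba(X)[:, 1]
        gap = np.abs(f - f.mean()).mean()
        assert table.values.sum() >= gap - 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            shap_importance(self._Additive(), np.zeros((2, 3)), ("a", "b", "c"),
                            n_samples=5)


class TestCompareAUC:
    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.9, 0.02, 100)
        _, p = compare_auc_distributions(a, a.copy())
        assert p >= 0.99

    def test_power_at_small_shift(self):
        """0.03 mean shift at sd 0.03, n=100: detected in >= 90% of runs."""
        detected = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            a = rng.normal(0.95, 0.03, 100)
            b = rng.normal(0.92, 0.03, 100)
            _, p = compare_auc_distributions(a, b)
            detected += p < 0.05
        assert detected >= 90

    def test_extreme_separation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 0.01, 100)
        _, p = compare_auc_distributions(a + 1.0, a)
        assert p < 1e-10

    def test_paired_variant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.95, 0.02, 50)
        b = a - 0.02 + rng.normal(0, 0.005, 50)
        _, p = compare_auc_distributions(a, b, paired=True)
        assert p < 0.01

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_auc_distributions(np.array([]), np.array([0.5]))

    def test_eval_result_summary(self):
        res = EvalResult(aucs=np.linspace(0.8, 1.0, 11), seeds=tuple(range(11)))
        s = res.summary()
        assert s["n_iter"] == 11
        assert s["mean"] == pytest.approx(0.9)
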