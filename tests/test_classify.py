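import itertools

import numpy as np
import pytest

from lnckit import classify
from lnckit.classify import ModelConfig
from lnckit.seqio import TranscriptRecord


def make_records(n_coding, n_noncoding):
    recs = [
        TranscriptRecord(id=f"c{i}", sequence="AUGAAAUAG", label="coding")
        for i in range(n_coding)
    ]
    recs += [
        TranscriptRecord(id=f"n{i}", sequence="CCCCCCCCC", label="noncoding")
        for i in range(n_noncoding)
    ]
    return recs


def separable_data(n, seed=0, d=2):
    """Two Gaussian blobs, linearly separable with wide margin."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-2.0, 0.4, size=(n // 2, d))
    X1 = rng.normal(2.0, 0.4, size=(n - n // 2, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestSplitTrainTest:
    def test_stratified_80_20(self):
        recs = make_records(50, 50)
        tr, te = classify.split_train_test(recs, 0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20
        assert sum(r.label == "coding" for r in tr) == 40

    def test_reproducible(self):
        recs = make_records(30, 30)
        a = classify.split_train_test(recs, 0.8, seed=5)
        b = classify.split_train_test(recs, 0.8, seed=5)
        assert [r.id for r in a[0]] == [r.id for r in b[0]]

    def test_half_split_balanced(self):
        recs = make_records(5, 5)
        tr, te = classify.split_train_test(recs, 0.5, seed=1)
        assert len(tr) == len(te) == 5
        assert sum(r.label == "coding" for r in tr) in (2, 3)
        assert set(r.id for r in tr) | set(r.id for r in te) == {r.id for r in recs}

    def test_single_class_rejected(self):
        with pytest.raises(classify.StratificationError):
            classify.split_train_test(make_records(10, 0), 0.8, seed=0)


class TestTrainAnnAndPredict:
    def test_separable_data_high_accuracy(self):
        X, y = separable_data(200, seed=1)
        cfg = ModelConfig(hidden_layers=(16,), seed=0)
        m = classify.train_ann(
            X[:160], y[:160], cfg, ["f0", "f1"], check_feature_count=False
        )
        p = classify.predict_proba(m, X[160:])
        acc = np.mean((p >= 0.5).astype(int) == y[160:])
        assert acc >= 0.95

    def test_constant_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(classify.StratificationError):
            classify.train_ann(
                X, np.zeros(20, dtype=int), ModelConfig(), ["a", "b"],
                check_feature_count=False,
            )

    def test_deterministic_under_seed(self):
        X, y = separable_data(100, seed=2)
        cfg = ModelConfig(hidden_layers=(8,), seed=3)
        m1 = classify.train_ann(X, y, cfg, ["a", "b"], check_feature_count=False)
        m2 = classify.train_ann(X, y, cfg, ["a", "b"], check_feature_count=False)
        np.testing.assert_array_equal(
            classify.predict_proba(m1, X), classify.predict_proba(m2, X)
        )

    def test_feature_count_config_mismatch(self):
        X, y = separable_data(60, seed=0, d=5)
        with pytest.raises(classify.ConfigurationError):
            classify.train_ann(X, y, ModelConfig(tier="basic"), [f"f{i}" for i in range(5)])

    def test_probabilities_in_unit_interval_and_order_equivariant(self):
        X, y = separable_data(80, seed=4)
        cfg = ModelConfig(hidden_layers=(8,), seed=0)
        m = classify.train_ann(X, y, cfg, ["a", "b"], check_feature_count=False)
        p = classify.predict_proba(m, X)
        assert np.all((p >= 0) & (p <= 1))
        rev = classify.predict_proba(m, X[::-1])
        np.testing.assert_allclose(rev, p[::-1])

    def test_column_mismatch_named(self):
        import pandas as pd

        X, y = separable_data(60, seed=0)
        cfg = ModelConfig(hidden_layers=(8,), seed=0)
        m = classify.train_ann(X, y, cfg, ["a", "b"], check_feature_count=False)
        with pytest.raises(classify.ConfigurationError, match="missing.*'b'"):
            classify.predict_proba(m, pd.DataFrame({"a": [1.0], "c": [2.0]}))


def confusion_oracle(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    return tp, fp, tn, fn


class TestComputeMetrics:
    def test_perfect_predictions(self):
        m = classify.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (m.precision, m.recall, m.specificity, m.f1, m.auroc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_ranked_auroc_one(self):
        m = classify.compute_metrics([1, 1, 0, 0], [0.9, 0.6, 0.4, 0.1])
        assert m.auroc == 1.0

    def test_all_tiny_cases_match_confusion_oracle(self):
        for y_true in itertools.product([0, 1], repeat=4):
            if len(set(y_true)) < 2:
                continue
            for y_pred in itertools.product([0, 1], repeat=4):
                p = [0.9 if v else 0.1 for v in y_pred]
                m = classify.compute_metrics(list(y_true), p)
                tp, fp, tn, fn = confusion_oracle(y_true, y_pred)
                assert m.precision == (tp / (tp + fp) if tp + fp else 0.0)
                assert m.recall == (tp / (tp + fn) if tp + fn else 0.0)
                assert m.specificity == (tn / (tn + fp) if tn + fp else 0.0)

    def test_random_ranker_auroc_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=10_000)
        p = rng.uniform(size=10_000)
        m = classify.compute_metrics(y, p)
        assert abs(m.auroc - 0.5) < 0.02

    def test_auroc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        p = rng.uniform(size=200)
        a = classify.compute_metrics(y, p).auroc
        b = classify.compute_metrics(y, np.exp(3 * p)).auroc
        assert a == pytest.approx(b)

    def test_single_class_auroc_undefined_with_partial_metrics(self):
        with pytest.raises(classify.AurocUndefinedError) as exc:
            classify.compute_metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert exc.value.metrics.recall == 1.0
        assert exc.value.metrics.auroc is None


class TestKfoldCv:
    def test_perfect_classifier_stub(self):
        X, y = separable_data(60, seed=0)

        class Stub:
            classes_ = np.array([0, 1])

            def predict_proba(self, Xs):
                # the first feature's sign determines the blob
                p = (Xs[:, 0] > 0).astype(float)
                return np.column_stack([1 - p, p])

        def trainer(Xa, ya):
            return classify.TrainedModel(
                config=ModelConfig(), feature_names=("a", "b"),
                scaler_mean=np.zeros(2), scaler_std=np.ones(2),
                estimator=Stub(), baseline=np.zeros(2),
            )

        res = classify.kfold_cv(X, y, 5, trainer, seed=0)
        assert res.accuracies == (1.0,) * 5

    def test_fold_sizes_differ_by_at_most_one(self):
        X, y = separable_data(47, seed=1)
        sizes = []

        def trainer(Xa, ya):
            sizes.append(len(Xa))
            cfg = ModelConfig(hidden_layers=(4,), seed=0, epochs=20)
            return classify.train_ann(Xa, ya, cfg, ["a", "b"], check_feature_count=False)

        classify.kfold_cv(X, y, 5, trainer, seed=0)
        test_sizes = [47 - s for s in sizes]
        assert max(test_sizes) - min(test_sizes) <= 1

    def test_mean_sd_recomputable(self):
        X, y = separable_data(50, seed=2)
        cfg = ModelConfig(hidden_layers=(4,), seed=0, epochs=30)
        trainer = lambda Xa, ya: classify.train_ann(
            Xa, ya, cfg, ["a", "b"], check_feature_count=False
        )
        res = classify.kfold_cv(X, y, 4, trainer, seed=0)
        assert res.mean == pytest.approx(np.mean(res.accuracies))
        assert res.sd == pytest.approx(np.std(res.accuracies))

    def test_k_exceeding_class_size_rejected(self):
        X, y = separable_data(8, seed=0)
        with pytest.raises(classify.StratificationError):
            classify.kfold_cv(X, y, 6, lambda a, b: None, seed=0)


class LinearStub:
    """f(x) = sigmoid(w . x); exact Shapley of the logit is w_j (x_j - b_j)."""

    classes_ = np.array([0, 1])

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def predict_proba(self, Xs):
        z = Xs @ self.w
        p = 1 / (1 + np.exp(-z))
        return np.column_stack([1 - p, p])


class TestShapImportance:
    def _model(self, w, d):
        return classify.TrainedModel(
            config=ModelConfig(), feature_names=tuple(f"f{i}" for i in range(d)),
            scaler_mean=np.zeros(d), scaler_std=np.ones(d),
            estimator=LinearStub(w), baseline=np.zeros(d),
        )

    def test_constant_feature_zero_importance(self, rng):
        m = self._model([1.0, 1.0], 2)
        X = np.column_stack([rng.normal(size=30), np.zeros(30)])
        imp = classify.shap_importance(m, X, n_samples=10, seed=0)
        assert imp["f1"] == 0.0

    def test_dominant_linear_coefficient(self, rng):
        m = self._model([3.0, 0.0], 2)
        X = rng.normal(size=(40, 2))
        imp = classify.shap_importance(m, X, n_samples=20, seed=0)
        assert imp["f0"] > 10 * imp["f1"]

    def test_non_negative_and_reproducible(self, rng):
        m = self._model([1.0, -2.0, 0.5], 3)
        X = rng.normal(size=(20, 3))
        a = classify.shap_importance(m, X, n_samples=5, seed=1)
        b = classify.shap_importance(m, X, n_samples=5, seed=1)
        assert a == b
        assert all(v >= 0 for v in a.values())

    def test_invalid_n_samples(self, rng):
        m = self._model([1.0], 1)
        with pytest.raises(ValueError):
            classify.shap_importance(m, np.ones((3, 1)), n_samples=0)


class TestRfe:
    def test_keep_all_returns_everything(self):
        X, y = separable_data(80, seed=0, d=3)
        cfg = ModelConfig(hidden_layers=(8,), seed=0, epochs=50)
        names = ["a", "b", "c"]
        out = classify.rfe(X, y, 3, cfg, names, n_shap_rows=10, n_shap_samples=4)
        assert sorted(out) == names

    def test_planted_signal_survives(self):
        successes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 150
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            X = rng.normal(size=(n, 10))
            X[:, 4] = y * 2.0 + rng.normal(0, 0.3, size=n)  # informative
            cfg = ModelConfig(hidden_layers=(8,), seed=seed, epochs=500)
            names = [f"f{i}" for i in range(10)]
            out = classify.rfe(X, y, 1, cfg, names, n_shap_rows=15, n_shap_samples=5)
            if out == ["f4"]:
                successes += 1
        assert successes >= 9

    def test_subset_of_input_names(self):
        X, y = separable_data(60, seed=3, d=5)
        cfg = ModelConfig(hidden_layers=(6,), seed=0, epochs=40)
        names = [f"f{i}" for i in range(5)]
        out = classify.rfe(X, y, 2, cfg, names, n_shap_rows=8, n_shap_samples=3)
        assert len(out) == 2 and set(out) <= set(names)


class TestBaselines:
    def test_all_kinds_learn_separable_data(self):
        X, y = separable_data(200, seed=5)
        for kind in ("svm", "naive_bayes"):
            m = classify.baseline_models(X[:160], y[:160], kind, seed=0)
            p = classify.predict_proba(m, X[160:])
            assert np.mean((p >= 0.5).astype(int) == y[160:]) >= 0.9
        cfg = ModelConfig(hidden_layers=(8,), seed=0)
        m = classify.train_ann(X[:160], y[:160], cfg, ["a", "b"], check_feature_count=False)
        p = classify.predict_proba(m, X[160:])
        assert np.mean((p >= 0.5).astype(int) == y[160:]) >= 0.9

    def test_nb_near_bayes_optimal_on_gaussian_data(self):
        # equal-variance Gaussians at +/- mu: Bayes accuracy = Phi(mu/sigma)
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        n, mu, sigma = 4000, 1.0, 1.0
        y = rng.integers(0, 2, size=n)
        X = rng.normal(mu * (2 * y - 1)[:, None], sigma, size=(n, 2))
        m = classify.baseline_models(X[:3000], y[:3000], "naive_bayes")
        p = classify.predict_proba(m, X[3000:])
        acc = np.mean((p >= 0.5).astype(int) == y[3000:])
        bayes = norm.cdf(np.sqrt(2) * mu / sigma)  # two independent features
        assert acc >= bayes - 0.05

    def test_unknown_kind(self):
        X, y = separable_data(20, seed=0)
        with pytest.raises(ValueError):
            classify.baseline_models(X, y, "forest")

    def test_svm_reproducible(self):
        X, y = separable_data(60, seed=1)
        a = classify.baseline_models(X, y, "svm", seed=2)
        b = classify.baseline_models(X, y, "svm", seed=2)
        np.testing.assert_array_equal(
            classify.predict_proba(a, X), classify.predict_proba(b, X)
        )


class TestModelArchive:
    def test_save_load_roundtrip(self, tmp_path):
        X, y = separable_data(60, seed=0)
        cfg = ModelConfig(hidden_layers=(8,), seed=0)
        m = classify.train_ann(X, y, cfg, ["a", "b"], check_feature_count=False)
        p = tmp_path / "model.joblib"
        classify.save_model(m, p)
        back = classify.load_model(p)
        np.testing.assert_array_equal(
            classify.predict_proba(back, X), classify.predict_proba(m, X)
        )
        assert back.feature_names == m.feature_names
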