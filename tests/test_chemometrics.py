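import numpy as np
import pandas as pd
import pytest
from scipy import stats

from berrylife import chemometrics
from berrylife.chemometrics import (
    CLASSIFIER_ROSTER,
    ClassificationResult,
    decision_surface,
    evaluate_classifiers,
    gb_day_regression,
    make_classifier,
    pca2,
    standardize,
    subset_search,
)


def _two_gaussians(rng, n=30, sep=8.0):
    X = np.vstack([
        rng.normal(0, 1, (n, 2)),
        rng.normal(sep, 1, (n, 2)),
    ])
    y = np.array([0] * n + [1] * n)
    return pd.DataFrame(X, columns=["f1", "f2"]), y


class TestStandardize:
    def test_population_sd_scaling(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, _ = standardize(df)
        assert out["x"].to_numpy() == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        out, _ = standardize(pd.DataFrame({"x": x}))
        assert out["x"].to_numpy() == pytest.approx(x, abs=1e-12)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="c"):
            standardize(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))


class TestPCA2:
    def test_collinear_data_first_component_explains_all(self):
        x = np.arange(10.0)
        res = pca2(np.column_stack([x, x]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_data_splits_variance(self, rng):
        X = rng.normal(size=(4000, 2))
        res = pca2(X)
        assert res.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(40, 5))
        a, b = pca2(X), pca2(X.copy())
        assert np.array_equal(a.scores, b.scores)
        for k in range(2):
            j = np.argmax(np.abs(a.loadings[k]))
            assert a.loadings[k, j] > 0

    def test_loadings_orthonormal_and_variance_nonincreasing(self, rng):
        X = rng.normal(size=(30, 6)) @ rng.normal(size=(6, 6))
        res = pca2(X)
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(2), atol=1e-10)
        evr = res.explained_variance_ratio
        assert evr[0] >= evr[1] and evr.sum() <= 1 + 1e-12

    def test_matches_eigendecomposition_oracle(self, rng):
        """Top-2 components agree with a direct covariance eigensolve."""
        X = rng.normal(size=(25, 4)) @ rng.normal(size=(4, 4))
        res = pca2(X)
        Z = (X - X.mean(0)) / X.std(0)
        w, V = np.linalg.eigh(np.cov(Z, rowvar=False))
        top = V[:, np.argsort(w)[::-1][:2]].T
        for k in range(2):
            dot = abs(np.dot(top[k], res.loadings[k]))
            assert dot == pytest.approx(1.0, abs=1e-9)
        # projecting on all components and back reproduces the data
        wfull, Vfull = np.linalg.eigh(np.cov(Z, rowvar=False))
        recon = (Z @ Vfull) @ Vfull.T
        np.testing.assert_allclose(recon, Z, atol=1e-9)

    def test_needs_two_features(self):
        with pytest.raises(ValueError):
            pca2(np.ones((5, 1)))


class TestEvaluateClassifiers:
    def test_separated_gaussians_high_accuracy(self, rng):
        X, y = _two_gaussians(rng)
        results = evaluate_classifiers(X, y, n_repeats=3, seed=1)
        assert results[0].overall_accuracy_pct >= 99.0

    def test_shuffled_labels_fall_to_chance(self, rng):
        X, y = _two_gaussians(rng, sep=8.0)
        y_shuf = rng.permutation(y)
        results = evaluate_classifiers(
            X, y_shuf, roster=["lda", "knn", "nearest_centroid"], n_repeats=3, seed=1
        )
        # binomial 99.9% bound of chance on the distinct samples (repeats of
        # K-fold reuse the same samples, so they are not independent trials)
        n = len(y_shuf)
        ci_hi = stats.binom.ppf(0.999, n, 0.5) / n * 100
        assert results[0].overall_accuracy_pct <= ci_hi

    def test_fixed_seed_bitwise_reproducible(self, rng):
        X, y = _two_gaussians(rng, sep=2.0)
        a = evaluate_classifiers(X, y, roster=["random_forest"], n_repeats=2, seed=3)[0]
        b = evaluate_classifiers(X, y, roster=["random_forest"], n_repeats=2, seed=3)[0]
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert np.array_equal(a.confusion, b.confusion)

    def test_accuracy_equals_confusion_trace_ratio(self, rng):
        X, y = _two_gaussians(rng, sep=1.0)
        for res in evaluate_classifiers(X, y, roster=["knn", "svm"], n_repeats=2, seed=0):
            trace_ratio = 100 * res.confusion.trace() / res.confusion.sum()
            assert res.overall_accuracy_pct == pytest.approx(trace_ratio)
            assert np.all(res.correct_per_class <= res.total_per_class)

    def test_class_smaller_than_k_suggests_smaller_k(self):
        X = pd.DataFrame({"f": np.arange(8.0), "g": np.arange(8.0)})
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="n_splits"):
            evaluate_classifiers(X, y, n_splits=5)

    def test_roster_has_ten_classifiers(self):
        assert len(CLASSIFIER_ROSTER) == 10
        for name in CLASSIFIER_ROSTER:
            make_classifier(name)

    def test_from_counts_arithmetic(self):
        res = ClassificationResult.from_counts([88, 86], [96, 96], labels=[1, 8])
        assert res.overall_accuracy_pct == pytest.approx(100 * 174 / 192)
        with pytest.raises(ValueError):
            ClassificationResult.from_counts([97], [96])


class TestSubsetSearch:
    def test_planted_informative_feature_recovered(self, rng):
        n = 40
        y = np.array([0] * n + [1] * n)
        X = pd.DataFrame(
            {
                "signal": np.concatenate([rng.normal(0, 1, n), rng.normal(6, 1, n)]),
                "noise1": rng.normal(size=2 * n),
                "noise2": rng.normal(size=2 * n),
            }
        )
        res = subset_search(X, y, max_subset_size=2, classifier="lda", seed=0)
        assert "signal" in res.best_subset
        assert res.best_accuracy_pct >= res.candidates["accuracy_pct"].max()

    def test_all_noise_near_chance(self, rng):
        y = np.array([0] * 25 + [1] * 25)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        res = subset_search(X, y, max_subset_size=1, classifier="lda", seed=0)
        assert res.best_accuracy_pct < 75.0

    def test_candidate_count_is_binomial_sum(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = subset_search(X, y, max_subset_size=2, classifier="nearest_centroid",
                            n_repeats=1, seed=0)
        assert len(res.candidates) == 4 + 6


class TestDecisionSurface:
    def test_linear_boundary_and_label_closure(self, rng):
        X, y = _two_gaussians(rng, n=20, sep=6.0)
        model = make_classifier("lda")
        model.fit(X.to_numpy(), y)
        xx, yy, labels = decision_surface(model, X.to_numpy(), grid_step=0.2)
        assert set(np.unique(labels)) <= set(np.unique(y))
        # a linear classifier yields one contiguous label block per row
        for row in labels:
            assert (np.diff(row) != 0).sum() <= 1

    def test_grid_spans_padded_bounds(self, rng):
        scores = rng.uniform(-1, 1, (30, 2))
        model = make_classifier("nearest_centroid")
        model.fit(scores, (scores[:, 0] > 0).astype(int))
        xx, yy, labels = decision_surface(model, scores, grid_step=0.05, padding=0.1)
        span = scores.max(0) - scores.min(0)
        assert xx[0] <= scores[:, 0].min() - 0.099 * span[0]
        assert xx[-1] >= scores[:, 0].max() + 0.099 * span[0] - 0.05
        assert labels.shape == (len(yy), len(xx))


class TestGBRegression:
    def test_noiseless_monotone_function_recovered(self, rng):
        x = rng.uniform(0, 10, 60)
        day = 2 * x + 1  # exact monotone map
        res = gb_day_regression(x.reshape(-1, 1), day, seed=0)
        assert res.r2 >= 0.99

    def test_independent_labels_near_zero_r2(self, rng):
        X = rng.normal(size=(60, 3))
        day = rng.choice([1, 4, 6, 8, 11], 60)
        res = gb_day_regression(X, day, seed=0)
        assert res.r2 <= 0.1

    def test_single_day_class_rejected(self):
        with pytest.raises(ValueError):
            gb_day_regression(np.ones((10, 2)), np.ones(10))
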