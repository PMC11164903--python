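"""Mahalanobis PCA-LDA classification and top-down component selection."""

import numpy as np
import pytest

from beanprint.discriminant import PCALDA, fit_pcalda, topdown_select
from beanprint.pca import NIPALSPCA


def gaussian_classes(seed, n_per_class=20, p=6, sep=4.0, classes=("A", "B")):
    """Isotropic Gaussian blobs with mean separation ``sep`` along axis 0."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(classes):
        mu = np.zeros(p)
        mu[0] = sep * i
        X.append(rng.normal(size=(n_per_class, p)) + mu)
        y += [c] * n_per_class
    return np.vstack(X), np.array(y, dtype=object)


class TestFit:
    def test_separable_classes_fit_perfectly(self):
        X, y = gaussian_classes(0, sep=25.0)
        model = fit_pcalda(X, y, k=3)
        assert model.score(X, y) == 1.0
        assert model.centroids_.shape == (2, 3)

    def test_centroids_recover_generating_means(self):
        X, y = gaussian_classes(1, n_per_class=400, sep=3.0)
        model = fit_pcalda(X, y, k=6)
        # project the true means with the fitted PCA; sampling error ~ 6/sqrt(400)
        mu_a = model.pca_.transform(np.array([[0, 0, 0, 0, 0, 0.0]]))[0]
        mu_b = model.pca_.transform(np.array([[3, 0, 0, 0, 0, 0.0]]))[0]
        assert np.linalg.norm(model.centroids_[0] - mu_a) < 0.35
        assert np.linalg.norm(model.centroids_[1] - mu_b) < 0.35

    def test_single_class_rejected(self):
        X, _ = gaussian_classes(2)
        with pytest.raises(ValueError, match="2 classes"):
            fit_pcalda(X, np.array(["A"] * len(X), dtype=object), k=2)

    def test_tiny_class_rejected(self):
        X, y = gaussian_classes(3)
        y[1:] = "B"
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_pcalda(X, y, k=2)

    def test_pooled_covariance_uses_n_minus_g_denominator(self):
        X, y = gaussian_classes(4, n_per_class=10, p=3)
        model = fit_pcalda(X, y, k=3)
        S = model.pca_.scores_
        scatter = np.zeros((3, 3))
        for c in ("A", "B"):
            dev = S[y == c] - S[y == c].mean(axis=0)
            scatter += dev.T @ dev
        np.testing.assert_allclose(model.pooled_cov_, scatter / (20 - 2), atol=1e-10)


class TestClassify:
    def test_centroid_spectrum_classified_with_zero_distance(self):
        X, y = gaussian_classes(5, sep=10.0)
        model = fit_pcalda(X, y, k=4)
        centroid_spectrum = model.pca_.inverse_transform(model.centroids_[1])
        labels, d2, tie = model.classify(centroid_spectrum)
        assert labels[0] == "B"
        assert d2[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_equidistant_point_breaks_tie_to_earlier_class(self):
        X, y = gaussian_classes(6, sep=8.0)
        model = fit_pcalda(X, y, k=2)
        midpoint = model.pca_.inverse_transform(model.centroids_.mean(axis=0))
        labels, _, tie = model.classify(midpoint)
        assert labels[0] == "A"  # earlier declared class
        assert tie[0]

    def test_matches_bruteforce_quadratic_forms(self):
        X, y = gaussian_classes(7, n_per_class=15, sep=2.0)
        model = fit_pcalda(X, y, k=5)
        Xnew, _ = gaussian_classes(8, n_per_class=15, sep=2.0)
        labels, d2, _ = model.classify(Xnew)
        scores = model.pca_.transform(Xnew)
        for i in range(len(Xnew)):
            dists = []
            for j in range(2):
                dev = scores[i] - model.centroids_[j]
                dists.append(dev @ np.linalg.inv(model.pooled_cov_) @ dev)
            np.testing.assert_allclose(d2[i], dists, atol=1e-8)
            assert labels[i] == model.classes_[int(np.argmin(dists))]

    def test_invariant_under_linear_map_of_score_space(self):
        X, y = gaussian_classes(9, n_per_class=25, sep=1.5)
        model = fit_pcalda(X, y, k=4)
        scores = model.pca_.transform(X)
        rng = np.random.default_rng(10)
        A = rng.normal(size=(4, 4))  # invertible w.h.p.
        d2_orig = model._distances_from_scores(scores)
        # transform scores, centroids and covariance consistently
        mapped = PCALDA(n_components=4)
        mapped.classes_ = model.classes_
        mapped.centroids_ = model.centroids_ @ A.T
        mapped.pooled_cov_ = A @ model.pooled_cov_ @ A.T
        mapped.pooled_cov_inv_ = np.linalg.inv(mapped.pooled_cov_)
        d2_mapped = mapped._distances_from_scores(scores @ A.T)
        np.testing.assert_allclose(d2_orig, d2_mapped, atol=1e-6)

    def test_identity_covariance_reduces_to_nearest_centroid(self):
        X, y = gaussian_classes(11, sep=3.0)
        model = fit_pcalda(X, y, k=3)
        model.pooled_cov_inv_ = np.eye(3)
        scores = model.pca_.transform(X)
        euclid = np.array(
            [
                model.classes_[
                    int(np.argmin([np.sum((s - c) ** 2) for c in model.centroids_]))
                ]
                for s in scores
            ],
            dtype=object,
        )
        np.testing.assert_array_equal(model.predict(X), euclid)

    def test_training_accuracy_grows_with_informative_component(self):
        # class signal lives on feature axis 3 => appears in a later PC
        rng = np.random.default_rng(12)
        n = 40
        X = rng.normal(size=(2 * n, 5)) * np.array([5.0, 3.0, 2.0, 0.5, 0.2])
        y = np.array(["A"] * n + ["B"] * n, dtype=object)
        X[n:, 3] += 4.0
        acc = [fit_pcalda(X, y, k=k).score(X, y) for k in (1, 2, 3, 4)]
        assert acc[3] > max(acc[:3])
        assert acc[3] > 0.95


class TestTopdownSelect:
    def test_dominant_pc_gives_single_candidate(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=(40, 1))
        X = u @ rng.normal(size=(1, 6)) * 100 + rng.normal(size=(40, 6)) * 1e-4
        y = np.array(["A", "B"] * 20, dtype=object)
        res = topdown_select(X, y, X, y, lo_pct=95, hi_pct=99.9)
        assert res.candidate_k == [1]
        assert res.chosen_k == 1

    def test_recovers_informative_depth(self):
        # informative direction in PC7 of a graded variance design
        rng = np.random.default_rng(14)
        scales = np.array([40, 30, 22, 16, 12, 9, 1.0, 0.6, 0.4, 0.3])
        n = 60
        X = rng.normal(size=(2 * n, 10)) * scales
        y = np.array(["A"] * n + ["B"] * n, dtype=object)
        X[n:, 6] += 6.0  # separation along the 7th-variance axis
        Xcv = rng.normal(size=(40, 10)) * scales
        ycv = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        Xcv[20:, 6] += 6.0
        res = topdown_select(X, y, Xcv, ycv, lo_pct=80, hi_pct=99.9)
        assert res.chosen_k >= 7
        # exhaustive oracle: chosen k maximizes cv accuracy
        best = max(res.cv_accuracy_at_k)
        assert res.cv_accuracy_at_k[res.candidate_k.index(res.chosen_k)] == best

    def test_ties_prefer_smaller_k(self):
        X, y = gaussian_classes(15, sep=50.0, p=8)  # everything is perfect
        res = topdown_select(X, y, X, y, lo_pct=50, hi_pct=99.9)
        assert len(res.candidate_k) > 1
        assert all(a <= res.cv_accuracy_at_k[0] for a in res.cv_accuracy_at_k)
        assert res.chosen_k == res.candidate_k[0]

    def test_candidate_count_capped(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(80, 40))
        y = np.array(["A", "B"] * 40, dtype=object)
        res = topdown_select(X, y, X, y, lo_pct=30, hi_pct=99.9, max_models=10)
        assert len(res.candidate_k) <= 10

    def test_truncated_model_equals_fresh_fit(self):
        X, y = gaussian_classes(17, n_per_class=30, p=8, sep=2.0)
        res = topdown_select(X, y, X, y, lo_pct=50, hi_pct=99.9)
        k = res.chosen_k
        fresh = fit_pcalda(X, y, k)
        np.testing.assert_allclose(
            res.model.pca_.components_, fresh.pca_.components_, atol=1e-7
        )
        np.testing.assert_allclose(res.model.centroids_, fresh.centroids_, atol=1e-7)
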