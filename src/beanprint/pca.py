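"""NIPALS principal component analysis with Hotelling's T-squared screening.

NIPALS (nonlinear iterative partial least squares) extracts principal
components one at a time from the mean-centred matrix: for each component it
alternates score/loading regressions until the score vector stabilises, then
deflates the matrix and records the share of total centred variance the
component captured. It is the classical chemometrics algorithm for wide
spectral matrices and, unlike a full eigendecomposition, stops after the k
components actually needed.

The estimator follows the scikit-learn transformer API. Centering always uses
the training mean only; held-out spectra are projected with the stored centre
vector.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge within the iteration budget."""


class NIPALSPCA(TransformerMixin, BaseEstimator):
    """Principal component analysis by sequential NIPALS deflation.

    Parameters
    ----------
    n_components : int or None
        Number of components to extract. When ``explained_target_pct`` is
        also given, acts as a cap on the component count.
    explained_target_pct : float or None
        Cumulative explained-variance stopping target in percent; extraction
        stops at the first component reaching it (or when ``n_components`` /
        the matrix rank is exhausted). Required when ``n_components`` is
        None.
    tol : float
        Convergence threshold on the relative change of the score vector.
    eigen_tol : float
        Secondary convergence threshold on the relative change of the
        component's explained sum of squares (the Rayleigh quotient). The
        quotient converges quadratically and remains accurate inside a
        near-degenerate eigen-subspace, where the score vector itself can
        rotate indefinitely between eigen-directions whose variances are
        numerically indistinguishable; deflation keeps later components
        exactly orthogonal either way.
    max_iter : int
        Iteration budget per component.

    Attributes
    ----------
    mean_ : ndarray, shape (n_features,)
        Training-set mean spectrum (the centre vector).
    components_ : ndarray, shape (k, n_features)
        Orthonormal loadings, one row per component. Sign convention: the
        largest-magnitude coefficient of each loading is positive.
    scores_ : ndarray, shape (n_samples, k)
        Training scores.
    explained_variance_pct_ : ndarray, shape (k,)
        Percent of total centred variance captured per component.
    n_iter_ : list of int
        NIPALS iterations used per component.
    """

    def __init__(
        self,
        n_components: int | None = None,
        explained_target_pct: float | None = None,
        tol: float = 1e-10,
        eigen_tol: float = 1e-12,
        max_iter: int = 10000,
    ):
        self.n_components = n_components
        self.explained_target_pct = explained_target_pct
        self.tol = tol
        self.eigen_tol = eigen_tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D matrix with at least 2 spectra")
        n, p = X.shape
        k_max = min(n - 1, p)
        if self.n_components is None and self.explained_target_pct is None:
            raise ValueError("give n_components or explained_target_pct")
        if self.n_components is None:
            k = k_max
        else:
            k = int(self.n_components)
            if not 1 <= k <= k_max:
                raise ValueError(
                    f"n_components must be in [1, {k_max}] for a {n}x{p} matrix"
                )

        self.mean_ = X.mean(axis=0)
        R = X - self.mean_  # residual matrix, deflated in place
        total_ss = float(np.sum(R * R))
        if total_ss == 0.0:
            raise ValueError("matrix has zero centred variance")

        loadings, scores, explained, iters = [], [], [], []
        for comp in range(k):
            col = int(np.argmax(np.sum(R * R, axis=0)))
            t = R[:, col].copy()
            if np.allclose(t, 0.0):
                break  # rank exhausted
            n_it = 0
            ss_old = float(t @ t)
            while True:
                pvec = R.T @ t / (t @ t)
                pvec /= np.linalg.norm(pvec)
                t_new = R @ pvec
                n_it += 1
                ss = float(t_new @ t_new)
                delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
                ss_delta = abs(ss - ss_old) / ss
                t = t_new
                if delta < self.tol or ss_delta < self.eigen_tol:
                    break
                ss_old = ss
                if n_it >= self.max_iter:
                    # Near-degenerate eigenpairs can rotate the score vector
                    # for ~1/gap iterations while the explained variance is
                    # already settled; accept the component if its variance
                    # motion is negligible on the explained-percent scale
                    # (< 1e-7 percentage points per iteration), otherwise
                    # fail loudly.
                    if abs(ss - ss_old) / total_ss < 1e-9:
                        break
                    raise ConvergenceError(
                        f"PC{comp + 1} did not converge in {self.max_iter} "
                        f"iterations (score change {delta:.2e}, explained-SS "
                        f"change {ss_delta:.2e})"
                    )
            # sign convention: largest-|coefficient| loading entry positive
            j = int(np.argmax(np.abs(pvec)))
            if pvec[j] < 0:
                pvec, t = -pvec, -t
            R -= np.outer(t, pvec)
            loadings.append(pvec)
            scores.append(t)
            explained.append(float(t @ t) / total_ss * 100.0)
            iters.append(n_it)
            if (
                self.explained_target_pct is not None
                and sum(explained) >= self.explained_target_pct
            ):
                break

        self.components_ = np.array(loadings)
        self.scores_ = np.array(scores).T
        self.explained_variance_pct_ = np.array(explained)
        self.n_iter_ = iters
        self.n_components_ = len(loadings)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        """Project spectra into score space: ``(X - mean) @ loadings.T``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"grid mismatch: model was fitted on {self.n_features_in_} "
                f"wavelengths, got {X.shape[1]}"
            )
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores @ self.components_ + self.mean_

    # ------------------------------------------------------------------
    def hotelling_t2(self, X=None, scores=None) -> np.ndarray:
        """Hotelling's T-squared of spectra relative to the training scores.

        ``T2 = sum_j score_j**2 / var(training score column j)`` over the
        retained components (sample variance, n-1 denominator).
        """
        if scores is None:
            if X is None:
                scores = self.scores_
            else:
                scores = self.transform(X)
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        var = self.scores_.var(axis=0, ddof=1)
        if np.any(var <= 0):
            raise ValueError("zero-variance score column: T2 undefined")
        return np.sum(scores**2 / var, axis=1)

    def t2_threshold(self, alpha: float = 0.05) -> float:
        """Small-sample F-approximation of the T2 control limit.

        ``k (n-1) / (n-k) * F_{1-alpha}(k, n-k)`` with n training spectra and
        k retained components — the limit drawn on chemometric influence
        plots.
        """
        n, k = self.scores_.shape
        if n <= k:
            raise ValueError("threshold needs more training spectra than components")
        f_crit = stats.f.ppf(1.0 - alpha, k, n - k)
        return k * (n - 1) / (n - k) * f_crit

    def outlier_mask(self, X=None, alpha: float = 0.05) -> np.ndarray:
        """Boolean mask of spectra whose T2 exceeds the (1-alpha) limit."""
        return self.hotelling_t2(X) > self.t2_threshold(alpha)

    def residual_variance_cv(
        self, X, n_segments: int = 20, seed: int | None = None
    ) -> np.ndarray:
        """Leave-random-segments-out residual variance per component count.

        Exploratory diagnostic: spectra are split into random segments; each
        segment is projected with a model fitted on the others and the mean
        squared reconstruction residual is accumulated for k = 1..n_components_.
        """
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(seed)
        order = rng.permutation(X.shape[0])
        segments = np.array_split(order, min(n_segments, X.shape[0]))
        k = self.n_components_
        press = np.zeros(k)
        for seg in segments:
            train = np.setdiff1d(order, seg)
            sub = NIPALSPCA(
                n_components=min(k, len(train) - 1, X.shape[1]),
                tol=self.tol,
                max_iter=self.max_iter,
            ).fit(X[train])
            centred = X[seg] - sub.mean_
            resid = centred.copy()
            for j in range(k):
                if j < sub.n_components_:
                    pj = sub.components_[j]
                    resid -= np.outer(resid @ pj, pj)
                press[j] += float(np.sum(resid**2))
        return press / X.size


# ---------------------------------------------------------------------------
# functional wrappers


def fit_nipals(
    X, k: int, tol: float = 1e-10, max_iter: int = 10000
) -> NIPALSPCA:
    """Fit a k-component NIPALS PCA (thin wrapper over :class:`NIPALSPCA`)."""
    return NIPALSPCA(n_components=k, tol=tol, max_iter=max_iter).fit(X)


def project(model: NIPALSPCA, X_new) -> np.ndarray:
    return model.transform(X_new)


def hotelling_t2(model: NIPALSPCA, scores_row) -> float:
    """T-squared of a single score vector against the model's training scores."""
    return float(model.hotelling_t2(scores=np.atleast_2d(scores_row))[0])
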