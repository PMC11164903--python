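"""PCA-LDA: Mahalanobis-distance discrimination in principal-component space.

The classifier first reduces the spectral matrix with NIPALS PCA, then models
each class by its centroid in score space under a pooled within-class
covariance (the classical LDA homoscedasticity assumption). A spectrum is
assigned to the class whose centroid is nearest in Mahalanobis distance

    d2(c) = (s - mu_c)' S_pooled^-1 (s - mu_c)

with uniform priors — training classes are balanced by construction, so prior
terms cancel. The number of retained components is chosen by a top-down
sweep: candidate counts cover the cumulative-explained-variance range from
95% to 99.9% (at most ten models) and the candidate with the best
cross-validation accuracy wins, smaller k on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .pca import NIPALSPCA

#: relative tolerance for declaring two class distances tied
TIE_RTOL = 1e-9


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance not invertible even after ridge regularization."""


def _class_order(y, classes=None) -> np.ndarray:
    y = np.asarray(y, dtype=object)
    if classes is not None:
        declared = np.asarray(list(classes), dtype=object)
        unknown = set(y) - set(declared)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")
        return declared
    # first-appearance order keeps tie-breaking deterministic and explicit
    _, idx = np.unique(y, return_index=True)
    return y[np.sort(idx)]


class PCALDA(ClassifierMixin, BaseEstimator):
    """Linear discriminant classification by Mahalanobis distance in PC space.

    Parameters
    ----------
    n_components : int
        Number of principal components retained before discrimination.
    classes : sequence or None
        Declared class order (ties break toward the earlier class). Default:
        first-appearance order in ``y``.
    ridge_condition_limit : float
        Pooled-covariance condition number above which a ridge of
        ``1e-8 * trace / k`` is added to the diagonal.
    tol, max_iter : NIPALS settings forwarded to :class:`NIPALSPCA`.

    Attributes
    ----------
    pca_ : fitted :class:`NIPALSPCA`
    classes_ : ndarray of class names, declared order
    centroids_ : ndarray, shape (n_classes, k) — class means in score space
    pooled_cov_ : ndarray, shape (k, k) — pooled within-class covariance,
        ``(n - n_classes)`` denominator, after any ridge
    pooled_cov_inv_ : its inverse
    """

    def __init__(
        self,
        n_components: int = 2,
        classes=None,
        ridge_condition_limit: float = 1e10,
        tol: float = 1e-10,
        max_iter: int = 10000,
    ):
        self.n_components = n_components
        self.classes = classes
        self.ridge_condition_limit = ridge_condition_limit
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.pca_ = NIPALSPCA(
            n_components=self.n_components, tol=self.tol, max_iter=self.max_iter
        ).fit(X)
        self._finalize(self.pca_.scores_, y)
        return self

    def _finalize(self, scores: np.ndarray, y) -> None:
        """Compute centroids and pooled covariance from training scores."""
        y = np.asarray(y, dtype=object)
        self.classes_ = _class_order(y, self.classes)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        k = scores.shape[1]
        centroids, scatter, n_total = [], np.zeros((k, k)), 0
        for c in self.classes_:
            sc = scores[y == c]
            if sc.shape[0] < 2:
                raise ValueError(f"class {c!r} has fewer than 2 spectra")
            mu = sc.mean(axis=0)
            centroids.append(mu)
            dev = sc - mu
            scatter += dev.T @ dev
            n_total += sc.shape[0]
        self.centroids_ = np.array(centroids)
        cov = scatter / (n_total - len(self.classes_))
        self.ridge_ = 0.0
        if np.linalg.cond(cov) > self.ridge_condition_limit:
            self.ridge_ = 1e-8 * np.trace(cov) / k
            cov = cov + self.ridge_ * np.eye(k)
        try:
            inv = np.linalg.inv(cov)
            if not np.all(np.isfinite(inv)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            raise SingularCovarianceError(
                "pooled within-class covariance is singular after regularization"
            ) from None
        self.pooled_cov_ = cov
        self.pooled_cov_inv_ = inv

    # ------------------------------------------------------------------
    def mahalanobis_sq(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each spectrum to each class centroid."""
        scores = self.pca_.transform(X)
        return self._distances_from_scores(scores)

    def _distances_from_scores(self, scores: np.ndarray) -> np.ndarray:
        d2 = np.empty((scores.shape[0], len(self.classes_)))
        for j, mu in enumerate(self.centroids_):
            dev = scores - mu
            d2[:, j] = np.einsum("ij,jk,ik->i", dev, self.pooled_cov_inv_, dev)
        return d2

    def predict(self, X) -> np.ndarray:
        labels, _, _ = self.classify(X)
        return labels

    def classify(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted class, per-class squared distances, and tie flags.

        Ties (distances equal within ``TIE_RTOL`` relative tolerance) break
        toward the earlier class in the declared order and are flagged.
        """
        d2 = self.mahalanobis_sq(X)
        best = np.argmin(d2, axis=1)
        dmin = d2[np.arange(d2.shape[0]), best]
        atol = TIE_RTOL * np.maximum(1.0, dmin)
        near = d2 <= (dmin + atol)[:, None]
        tie = near.sum(axis=1) > 1
        # earlier declared class wins on ties
        first_near = near.argmax(axis=1)
        labels = self.classes_[first_near]
        return labels, d2, tie

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=object)
        return float(np.mean(self.predict(X) == y))


# ---------------------------------------------------------------------------
# top-down component selection


@dataclass
class SelectionResult:
    """Outcome of the top-down PC-count sweep."""

    candidate_k: list[int]
    explained_at_k: list[float]  # cumulative explained variance (%) per candidate
    cv_accuracy_at_k: list[float]
    chosen_k: int
    model: PCALDA = field(repr=False, default=None)

    @property
    def chosen_explained_pct(self) -> float:
        return self.explained_at_k[self.candidate_k.index(self.chosen_k)]


def topdown_select(
    X_train,
    y_train,
    X_cv,
    y_cv,
    lo_pct: float = 95.0,
    hi_pct: float = 99.9,
    max_models: int = 10,
    max_components: int = 30,
    classes=None,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> SelectionResult:
    """Sweep PC counts covering ``lo_pct``..``hi_pct`` cumulative variance.

    Candidates run from the smallest k reaching ``lo_pct`` to the smallest k
    reaching ``hi_pct`` (evenly thinned to at most ``max_models``); one
    PCA-LDA is evaluated per candidate on the cross-validation split and the
    best accuracy wins, smaller k on ties. Because NIPALS components are
    nested, the PCA is fitted once to the largest candidate and truncated —
    each candidate model is identical to fitting it from scratch.

    When the residual spectrum is so flat that ``hi_pct`` would need more
    than ``max_components`` PCs (a noise floor, not structure), the sweep is
    truncated there with a warning — discriminating in hundreds of noise
    dimensions is never useful.
    """
    X_train = np.asarray(X_train, dtype=float)
    k_cap = min(int(max_components), X_train.shape[0] - 1, X_train.shape[1])
    pca = NIPALSPCA(
        n_components=k_cap, explained_target_pct=hi_pct, tol=tol, max_iter=max_iter
    ).fit(X_train)
    cum = np.cumsum(pca.explained_variance_pct_)
    if cum[-1] < hi_pct:
        warnings.warn(
            f"only {cum[-1]:.2f}% variance reachable with {pca.n_components_} "
            f"PCs; candidate list truncated below the {hi_pct}% target",
            stacklevel=2,
        )
    k_lo = int(np.searchsorted(cum, lo_pct) + 1)
    k_lo = min(k_lo, pca.n_components_)
    k_hi = pca.n_components_
    candidates = np.arange(k_lo, k_hi + 1)
    if candidates.size > max_models:
        candidates = np.unique(
            np.round(np.linspace(k_lo, k_hi, max_models)).astype(int)
        )

    cv_scores = pca.transform(np.asarray(X_cv, dtype=float))
    y_cv = np.asarray(y_cv, dtype=object)
    models, accuracies, explained = [], [], []
    for k in candidates:
        model = PCALDA(n_components=int(k), classes=classes, tol=tol, max_iter=max_iter)
        model.pca_ = _truncated_pca(pca, int(k))
        model._finalize(pca.scores_[:, :k], y_train)
        pred = model.classes_[
            np.argmin(model._distances_from_scores(cv_scores[:, :k]), axis=1)
        ]
        models.append(model)
        accuracies.append(float(np.mean(pred == y_cv)))
        explained.append(float(cum[k - 1]))
    best = int(np.argmax(accuracies))  # argmax takes the first max → smaller k
    return SelectionResult(
        candidate_k=[int(k) for k in candidates],
        explained_at_k=explained,
        cv_accuracy_at_k=accuracies,
        chosen_k=int(candidates[best]),
        model=models[best],
    )


def _truncated_pca(pca: NIPALSPCA, k: int) -> NIPALSPCA:
    """First-k-component view of a fitted NIPALS model (components are nested)."""
    sub = NIPALSPCA(n_components=k, tol=pca.tol, max_iter=pca.max_iter)
    sub.mean_ = pca.mean_
    sub.components_ = pca.components_[:k]
    sub.scores_ = pca.scores_[:, :k]
    sub.explained_variance_pct_ = pca.explained_variance_pct_[:k]
    sub.n_iter_ = pca.n_iter_[:k]
    sub.n_components_ = k
    sub.n_features_in_ = pca.n_features_in_
    return sub


# ---------------------------------------------------------------------------
# functional wrappers


def fit_pcalda(X_train, y_train, k: int, classes=None) -> PCALDA:
    """Fit a k-component PCA-LDA (thin wrapper over :class:`PCALDA`)."""
    return PCALDA(n_components=k, classes=classes).fit(X_train, y_train)


def classify(model: PCALDA, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return model.classify(X)
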