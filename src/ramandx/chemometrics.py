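"""PCA and leave-one-out nearest-centroid classification of spectra.

The classification protocol: for every spectrum, fit a PCA model on all
*other* spectra, project both the training spectra and the held-out one
onto the first ``k`` components, and assign the held-out spectrum to the
class whose score-space centroid is nearest (Euclidean). The tally of
(true, predicted) pairs is the confusion matrix; its trace over the total
is the classification efficiency.

Per-fold PCA is computed in the dual (Gram-matrix) space: the centered
Gram matrix of each fold is obtained by rank-one updates of the full Gram
matrix, and its leading eigenpairs by a block subspace iteration
warm-started from the full-data solution. This is algebraically identical
to an SVD of the centered fold matrix (verified against an explicit
fold-by-fold oracle in the test suite) but avoids refactorizing the full
spectra matrix a thousand times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpectrumSet, Spectrum

__all__ = [
    "PCAModel",
    "ConfusionMatrix",
    "fit_pca",
    "project",
    "loocv_classify",
    "efficiency",
]


@dataclass(frozen=True)
class PCAModel:
    """Mean spectrum, ordered orthonormal loadings and variance fractions."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (k, n_points), PC1..PCk
    explained_variance_fractions: np.ndarray  # (k,)

    @property
    def k(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predicted-vs-true counts; rows = true class, columns = predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (n_classes, n_classes) int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
        }


def efficiency(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified spectra: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def fit_pca(sset: SpectrumSet, k: int) -> PCAModel:
    """PCA of a spectrum set via SVD of the mean-centered data matrix.

    Loadings are the top-``k`` right singular directions; each is sign-fixed
    so its largest-magnitude element is positive. The explained-variance
    fraction of PC i is sigma_i^2 over the sum of all squared singular
    values.
    """
    X = sset.matrix()
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n_spectra, got k={k}, n={n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    loadings = vt[:k].copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    evf = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAModel(mean_spectrum=mean, loadings=loadings, explained_variance_fractions=evf)


def project(model: PCAModel, data: SpectrumSet | Spectrum) -> np.ndarray:
    """Scores of a set (n, k) or a single spectrum (k,) under a PCA model."""
    if isinstance(data, SpectrumSet):
        if data.axis.n_points != model.mean_spectrum.size:
            raise ValueError("axis does not match the PCA model")
        return (data.matrix() - model.mean_spectrum) @ model.loadings.T
    if data.axis.n_points != model.mean_spectrum.size:
        raise ValueError("axis does not match the PCA model")
    return (data.intensities - model.mean_spectrum) @ model.loadings.T


# ---------------------------------------------------------------------------
# leave-one-out classification
# ---------------------------------------------------------------------------

def _nearest_centroid(
    scores: np.ndarray,
    labels: np.ndarray,
    held_out_score: np.ndarray,
    class_labels: list[str],
    metric: str,
) -> str:
    """Assign the held-out score to the nearest class centroid.

    Ties go to the lexicographically smallest label. The optional
    Mahalanobis variant whitens distances with the pooled within-class
    covariance of the training scores.
    """
    if metric == "mahalanobis":
        k = scores.shape[1]
        pooled = np.zeros((k, k))
        dof = 0
        for lbl in class_labels:
            member = scores[labels == lbl]
            if member.shape[0] > 1:
                pooled += (member - member.mean(axis=0)).T @ (member - member.mean(axis=0))
                dof += member.shape[0] - 1
        pooled = pooled / max(dof, 1) + 1e-12 * np.eye(k)
        whiten = np.linalg.cholesky(np.linalg.inv(pooled)).T
    else:
        whiten = None

    best_label = None
    best_dist = np.inf
    for lbl in sorted(class_labels):  # sorted: ties fall to the smallest label
        centroid = scores[labels == lbl].mean(axis=0)
        diff = held_out_score - centroid
        if whiten is not None:
            diff = whiten @ diff
        d = float(diff @ diff)
        if best_label is None or d < best_dist:
            best_dist = d
            best_label = lbl
    return best_label


def loocv_classify(
    sset: SpectrumSet,
    k: int = 3,
    *,
    metric: str = "euclidean",
    tol: float = 1e-9,
    max_iter: int = 500,
) -> ConfusionMatrix:
    """Leave-one-out PCA nearest-centroid classification of a labeled set."""
    if metric not in ("euclidean", "mahalanobis"):
        raise ValueError(f"unknown metric {metric!r}")
    X = sset.matrix()
    labels = np.array(sset.labels)
    n = X.shape[0]
    class_labels = sorted(set(labels))
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    for lbl in class_labels:
        if (labels == lbl).sum() < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 members")
    if not 1 <= k < n - 1:
        raise ValueError(f"need 1 <= k < n - 1, got k={k}, n={n}")

    G = X @ X.T
    block = min(k + 4, n - 2)
    # warm start: leading eigenvectors of the full centered Gram matrix
    Gc = _center_gram(G)
    V0 = _top_eigenvectors(lambda V: Gc @ V, n, block, tol, max_iter)

    label_index = {lbl: i for i, lbl in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)

    for i in range(n):
        idx = np.ones(n, dtype=bool)
        idx[i] = False
        m = n - 1
        Gs = G[np.ix_(idx, idx)]
        r = Gs.sum(axis=1)
        t = float(r.sum())
        # centered fold Gram: Hc = Gs - (r 1' + 1 r')/m + t/m^2 11'
        Hc = Gs - (r[:, None] + r[None, :]) / m + t / (m * m)
        warm = V0[idx]
        V, lam = _top_eigenpairs(Hc, warm, k, tol, max_iter)
        sig = np.sqrt(np.clip(lam, 0.0, None))
        train_scores = V * sig  # rows: training spectra, cols: PC1..PCk

        g = G[i, idx]
        a = float(g.sum()) / m  # x_i . mu
        w = g - a - r / m + t / (m * m)
        with np.errstate(divide="ignore", invalid="ignore"):
            held_out = np.where(sig > 0, (V.T @ w) / np.where(sig > 0, sig, 1.0), 0.0)

        pred = _nearest_centroid(train_scores, labels[idx], held_out, class_labels, metric)
        counts[label_index[labels[i]], label_index[pred]] += 1

    return ConfusionMatrix(labels=tuple(class_labels), counts=counts)


def _center_gram(G: np.ndarray) -> np.ndarray:
    n = G.shape[0]
    r = G.sum(axis=1)
    t = float(r.sum())
    return G - (r[:, None] + r[None, :]) / n + t / (n * n)


def _top_eigenvectors(matvec, n: int, block: int, tol: float, max_iter: int) -> np.ndarray:
    rng = np.random.default_rng(0)  # fixed: only a subspace-iteration start
    V = rng.standard_normal((n, block))
    V, _ = np.linalg.qr(V)
    for _ in range(max_iter):
        W = matvec(V)
        Q, _ = np.linalg.qr(W)
        HQ = matvec(Q)
        T = Q.T @ HQ
        evals, S = np.linalg.eigh(T)
        order = np.argsort(evals)[::-1]
        V_new = Q @ S[:, order]
        lam = evals[order]
        resid = HQ @ S[:, order] - V_new * lam
        scale = max(abs(lam[0]), 1e-300)
        if np.linalg.norm(resid, axis=0).max() <= tol * scale:
            return V_new
        V = V_new
    return V


def _top_eigenpairs(
    H: np.ndarray, warm: np.ndarray, k: int, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenpairs of a symmetric PSD matrix by block subspace iteration."""
    V = warm
    # re-orthonormalize the warm start (one row was dropped)
    V, _ = np.linalg.qr(V)
    lam = np.zeros(V.shape[1])
    for _ in range(max_iter):
        W = H @ V
        Q, _ = np.linalg.qr(W)
        HQ = H @ Q
        T = Q.T @ HQ
        evals, S = np.linalg.eigh(T)
        order = np.argsort(evals)[::-1]
        V = Q @ S[:, order]
        lam = evals[order]
        resid = HQ @ S[:, order] - V * lam
        scale = max(abs(lam[0]), 1e-300)
        if np.linalg.norm(resid[:, :k], axis=0).max() <= tol * scale:
            break
    return V[:, :k], lam[:k]
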