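"""k-Shape clustering of z-normalized time series.

The shape-based distance (SBD) between two z-normalized series is

    SBD(x, y) = 1 - max_s NCC_c(x, y; s)

where NCC_c is the coefficient-normalized cross-correlation over all
integer shifts s, making the distance shift- and scale-invariant.
Cluster centroids are refined by shape extraction: members are aligned
to the current centroid at their best shift and the new centroid is the
dominant eigenvector of the centred Gram matrix of the aligned members
(the series maximizing the summed squared correlation to the cluster).

The per-member similarity reported alongside the assignment is
``(1 + NCC_max) / 2`` mapped to [0, 1]; thresholding it extracts
high-confidence cluster prototypes downstream.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import irfft, rfft
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .features import zscore


def _ncc_c(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficient-normalized cross-correlation of two 1-D series over
    all shifts (length 2T-1); zero where either norm vanishes."""
    T = x.size
    den = np.linalg.norm(x) * np.linalg.norm(y)
    if den < 1e-12:
        return np.zeros(2 * T - 1)
    size = 1 << (2 * T - 1).bit_length()
    cc = irfft(rfft(x, size) * np.conj(rfft(y, size)), size)
    cc = np.concatenate((cc[-(T - 1):], cc[:T])) if T > 1 else cc[:1]
    return cc / den


def sbd(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Shape-based distance and the y-aligned-to-x series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cc = _ncc_c(x, y)
    idx = int(np.argmax(cc))
    dist = 1.0 - float(cc[idx])
    shift = idx - (x.size - 1)
    aligned = np.zeros_like(y)
    if shift >= 0:
        aligned[shift:] = y[: y.size - shift]
    else:
        aligned[:shift] = y[-shift:]
    return dist, aligned


def _shape_extraction(members: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """New centroid: dominant eigenvector of the centred Gram of the
    members aligned to the current centroid (sign fixed towards the
    aligned mean), z-normalized."""
    if members.shape[0] == 0:
        return centroid
    aligned = np.empty_like(members)
    for i, m in enumerate(members):
        if np.linalg.norm(centroid) < 1e-12:
            aligned[i] = m
        else:
            _, aligned[i] = sbd(centroid, m)
    T = members.shape[1]
    S = aligned.T @ aligned
    Q = np.eye(T) - np.ones((T, T)) / T
    M = Q @ S @ Q
    _, vecs = np.linalg.eigh(M)
    new = vecs[:, -1]
    if new @ aligned.mean(axis=0) < 0:
        new = -new
    return zscore(new)


class KShape(BaseEstimator, ClusterMixin):
    """k-Shape clustering estimator (sklearn API).

    Parameters
    ----------
    n_clusters : int
        Number of shape clusters (typically several times the number of
        crop classes, since clusters capture curve *types*).
    max_iter : int
        Assignment/refinement iteration cap.
    random_state : int
        Seed for the random initial assignment; runs are deterministic
        for a fixed seed and input order.

    Attributes
    ----------
    labels_ : (n,) cluster index per series.
    cluster_centers_ : (k, T) z-normalized centroids.
    similarity_ : (n,) ``(1 + NCC_max) / 2`` to the own centroid, in [0, 1].
    """

    def __init__(self, n_clusters: int = 9, max_iter: int = 100, n_init: int = 5,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, T = X.shape
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n={n} series")
        Xz = zscore(X)
        best = None
        for trial in range(max(self.n_init, 1)):
            labels, centroids, ncc = self._fit_once(
                Xz, np.random.default_rng((self.random_state, trial))
            )
            inertia = float(np.sum(1.0 - ncc))
            if best is None or inertia < best[0] - 1e-12:
                best = (inertia, labels, centroids, ncc)
        self.inertia_, self.labels_, self.cluster_centers_, ncc = best
        self.similarity_ = (1.0 + ncc) / 2.0
        self.n_features_in_ = T
        return self

    def _fit_once(self, Xz, rng):
        n, T = Xz.shape
        labels = rng.integers(0, self.n_clusters, size=n)
        centroids = np.zeros((self.n_clusters, T))
        for _ in range(self.max_iter):
            for k in range(self.n_clusters):
                centroids[k] = _shape_extraction(Xz[labels == k], centroids[k])
            new_labels, ncc = self._assign(Xz, centroids)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        _, ncc = self._assign(Xz, centroids)
        return labels, centroids, ncc

    @staticmethod
    def _assign(Xz, centroids):
        n = Xz.shape[0]
        k = centroids.shape[0]
        best = np.zeros(n, dtype=int)
        best_ncc = np.full(n, -np.inf)
        for j in range(k):
            for i in range(n):
                cc = _ncc_c(Xz[i], centroids[j]).max()
                if cc > best_ncc[i] + 1e-12:
                    best_ncc[i] = cc
                    best[i] = j
        return best, np.clip(best_ncc, -1.0, 1.0)

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        Xz = zscore(np.atleast_2d(np.asarray(X, dtype=float)))
        labels, _ = self._assign(Xz, self.cluster_centers_)
        return labels

    def similarity_to_own_centroid(self, X):
        """(1 + NCC_max)/2 of each series to its nearest centroid."""
        check_is_fitted(self, "cluster_centers_")
        Xz = zscore(np.atleast_2d(np.asarray(X, dtype=float)))
        _, ncc = self._assign(Xz, self.cluster_centers_)
        return (1.0 + ncc) / 2.0
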