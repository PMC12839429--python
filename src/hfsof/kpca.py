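"""RBF-kernel principal component analysis.

Kernel entries are ``exp(-gamma * ||a - b||^2)`` with ``gamma = 1/d`` by
default. The training kernel is double-centered, eigendecomposed, and only
strictly positive eigenvalues are retained. New points are projected via the
cross-kernel centered with training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

#: eigenvalues below this fraction of the largest are treated as zero
EIGENVALUE_RTOL = 1e-10


@dataclass
class KpcaModel:
    X_train: np.ndarray          # N x d standardized training features
    gamma: float
    eigenvalues: np.ndarray      # length p, strictly positive, descending
    eigenvectors: np.ndarray     # N x p, orthonormal columns
    train_col_means: np.ndarray  # column means of the uncentered train kernel
    train_grand_mean: float

    @property
    def p(self) -> int:
        return int(self.eigenvalues.shape[0])

    @property
    def feature_names(self) -> list[str]:
        return [f"kpc_{j + 1:04d}" for j in range(self.p)]


@dataclass
class Embedding:
    """Kernel principal component scores, one row per sample."""

    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.size and not np.all(np.isfinite(self.Z)):
            raise ValueError("embedding contains non-finite values")


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix ``exp(-gamma * ||a_i - b_j||^2)``."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share the feature dimension")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("kernel inputs must be finite")
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-gamma * sq)


def _fix_eigenvector_signs(U: np.ndarray) -> np.ndarray:
    # flip each column so its largest-magnitude entry is positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def fit_kpca(
    X_train: np.ndarray, p_requested: int, gamma: float | None = None
) -> KpcaModel:
    """Fit kernel PCA on standardized training data.

    ``gamma`` defaults to ``1/d``. Retains ``p = min(p_requested,
    #positive eigenvalues)`` components; raises ``"degenerate kernel"`` when
    the centered kernel has no positive eigenvalue above tolerance.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("need a 2-D training matrix with N >= 2")
    if p_requested < 1:
        raise ValueError("p_requested must be >= 1")
    n, d = X_train.shape
    if gamma is None:
        gamma = 1.0 / d

    K = rbf_kernel(X_train, X_train, gamma)
    col_means = K.mean(axis=0)
    grand_mean = float(K.mean())
    K_centered = K - col_means[None, :] - col_means[:, None] + grand_mean

    eigvals, eigvecs = eigh(K_centered)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = EIGENVALUE_RTOL * max(eigvals[0], 0.0)
    positive = eigvals > tol
    if not positive.any():
        raise ValueError("degenerate kernel: no positive eigenvalues")
    p = min(p_requested, int(positive.sum()))
    U = _fix_eigenvector_signs(eigvecs[:, :p])
    return KpcaModel(
        X_train=X_train,
        gamma=float(gamma),
        eigenvalues=eigvals[:p].copy(),
        eigenvectors=U,
        train_col_means=col_means,
        train_grand_mean=grand_mean,
    )


def training_embedding(model: KpcaModel) -> Embedding:
    """Scores of the training rows: ``Z = U * sqrt(lambda)``."""
    Z = model.eigenvectors * np.sqrt(model.eigenvalues)[None, :]
    return Embedding(Z=Z)


def transform_kpca(model: KpcaModel, X_new: np.ndarray) -> Embedding:
    """Project new points via the training-centered cross-kernel."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} features, model expects "
            f"{model.X_train.shape[1]}"
        )
    if X_new.shape[0] == 0:
        return Embedding(Z=np.zeros((0, model.p)))
    K_new = rbf_kernel(X_new, model.X_train, model.gamma)
    row_means = K_new.mean(axis=1, keepdims=True)
    K_centered = (
        K_new - model.train_col_means[None, :] - row_means + model.train_grand_mean
    )
    Z = K_centered @ (model.eigenvectors / np.sqrt(model.eigenvalues)[None, :])
    return Embedding(Z=Z)
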