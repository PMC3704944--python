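"""Classical multidimensional scaling and Gaussian-kernel SVM classification.

The fused dissimilarity matrix is not guaranteed to be Euclidean, so it is
projected by classical MDS (principal coordinates analysis): double-center
the squared dissimilarities, eigendecompose, and keep coordinates for the
strictly positive eigenvalues.  The embedding dimension actually used for
classification is chosen by minimizing the stratified k-fold
cross-validation error of a radial-basis-function SVM over leading
principal-coordinate prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .matrix import DissimilarityMatrix

#: Relative tolerance deciding which eigenvalues count as positive.
EIGENVALUE_RTOL = 1e-9


class EmbeddingError(ValueError):
    """Raised when the spectrum cannot support an embedding."""


@dataclass(frozen=True)
class Embedding:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``coords`` has one column per strictly positive eigenvalue, ordered by
    descending eigenvalue and scaled so Euclidean distances approximate the
    input dissimilarities; ``eigenvalues`` is the full descending spectrum.
    """

    drug_ids: tuple[str, ...]
    coords: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_positive(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class CVCurve:
    """Cross-validated error as a function of embedding dimension."""

    dims: tuple[int, ...]
    errors: tuple[float, ...]
    selected_dim: int

    @property
    def selected_error(self) -> float:
        return self.errors[self.dims.index(self.selected_dim)]


def cmds_embed(K: DissimilarityMatrix) -> Embedding:
    """Classical MDS / principal coordinates analysis of a dissimilarity
    matrix.

    Computes ``B = -1/2 J K^2 J`` (``J`` the centering matrix), takes its
    eigendecomposition, and returns coordinates ``V sqrt(L)`` over the
    eigenvalues exceeding ``EIGENVALUE_RTOL`` times the largest one.
    Negative eigenvalues (non-Euclidean input) are dropped, not corrected.
    """
    D = K.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals.size == 0 or eigvals[0] <= 0:
        raise EmbeddingError("degenerate embedding: no positive eigenvalues")
    positive = eigvals > EIGENVALUE_RTOL * eigvals[0]
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    return Embedding(
        drug_ids=K.ids,
        coords=coords,
        eigenvalues=eigvals,
    )


def train_svm(
    coords: np.ndarray,
    labels,
    gamma: float | str = "scale",
    C: float = 1.0,
) -> SVC:
    """Fit a multiclass SVM with Gaussian kernel ``exp(-gamma ||x-y||^2)``.

    ``gamma='scale'`` uses ``1 / (d * var(coords))``; ``C`` defaults to 1.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires at least two classes")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    clf = SVC(kernel="rbf", gamma=gamma, C=C)
    clf.fit(coords, labels)
    return clf


def predict(clf: SVC, coords: np.ndarray) -> list[str]:
    return clf.predict(np.atleast_2d(np.asarray(coords, dtype=float))).tolist()


def select_dimension(
    emb: Embedding,
    labels,
    folds: int = 6,
    dims: list[int] | None = None,
    seed: int = 0,
    gamma: float | str = "scale",
    C: float = 1.0,
) -> CVCurve:
    """Choose the embedding dimension by cross-validated SVM error.

    For each candidate dimension ``i`` the classifier sees only the first
    ``i`` principal coordinates; the fold assignment (stratified, seeded)
    and the SVM hyperparameters are held fixed across dimensions.  The
    selected dimension is the arg-min of the error curve, ties broken
    toward the smaller dimension.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != emb.coords.shape[0]:
        raise ValueError("label count does not match embedding size")
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < folds]
    if too_small.size:
        raise ValueError(
            f"class(es) smaller than {folds} members: {', '.join(too_small)}"
        )
    d_max = emb.n_positive
    if dims is None:
        dims = list(range(1, d_max + 1))
    if any(d < 1 or d > d_max for d in dims):
        raise ValueError(f"dims must lie in 1..{d_max}")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(emb.coords, labels))
    errors = []
    for d in dims:
        X = emb.coords[:, :d]
        wrong = 0
        for train_idx, test_idx in splits:
            clf = SVC(kernel="rbf", gamma=gamma, C=C)
            clf.fit(X[train_idx], labels[train_idx])
            wrong += int(np.sum(clf.predict(X[test_idx]) != labels[test_idx]))
        errors.append(wrong / labels.shape[0])
    best = int(np.argmin(errors))  # argmin takes the first, i.e. smallest dim
    return CVCurve(
        dims=tuple(dims),
        errors=tuple(errors),
        selected_dim=dims[best],
    )
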