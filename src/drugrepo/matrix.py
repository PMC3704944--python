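"""Labelled symmetric dissimilarity matrices.

All pairwise layers (chemical, target, expression) and their fusion are
carried as :class:`DissimilarityMatrix`: a square, symmetric, zero-diagonal
matrix of real dissimilarities together with the ordered list of drug ids
labelling its rows and columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-12


class MatrixError(ValueError):
    """Raised when a matrix violates the dissimilarity-matrix contract."""


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric zero-diagonal matrix over an ordered set of drug ids.

    Parameters
    ----------
    ids
        Ordered drug identifiers labelling rows and columns.
    values
        Square float matrix; must be symmetric within ``1e-12`` and have a
        zero diagonal.
    """

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise MatrixError(f"matrix must be square, got shape {values.shape}")
        if len(ids) != values.shape[0]:
            raise MatrixError(
                f"{len(ids)} ids for a {values.shape[0]}x{values.shape[1]} matrix"
            )
        if len(set(ids)) != len(ids):
            raise MatrixError("duplicate drug ids")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise MatrixError(f"matrix asymmetric beyond tolerance ({asym:.3e})")
        if values.size and np.abs(np.diag(values)).max(initial=0.0) > SYMMETRY_TOL:
            raise MatrixError("matrix diagonal is not zero")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, drug_id: str) -> int:
        return self.ids.index(drug_id)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, keep: list[str] | tuple[str, ...]) -> "DissimilarityMatrix":
        """Principal submatrix over ``keep``, preserving the given order."""
        idx = [self.ids.index(k) for k in keep]
        return DissimilarityMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def range_normalize(matrix: np.ndarray) -> np.ndarray:
    """Range-normalize a symmetric matrix over its off-diagonal entries.

    Maps off-diagonal entries through ``(x - min) / (max - min)`` so the
    result lies in ``[0, 1]``; a degenerate range (``max == min``) maps every
    entry to zero.  The diagonal stays zero.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        return np.zeros_like(matrix)
    off = ~np.eye(n, dtype=bool)
    lo, hi = matrix[off].min(), matrix[off].max()
    out = np.zeros_like(matrix)
    if hi > lo:
        out[off] = (matrix[off] - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out
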