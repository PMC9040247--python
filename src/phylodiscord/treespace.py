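"""All-pairs Robinson-Foulds matrices and classical PCoA tree-space embedding."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import treekit
from .treekit import Tree, TreeError


class TreeSpaceError(Exception):
    pass


def rf_matrix(trees: list[Tree], normalized: bool = True,
              prune_to_common: bool = False, labels=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise RF distances."""
    n = len(trees)
    if labels is None:
        labels = [f"tree{i + 1}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = treekit.rf_distance(trees[i], trees[j], normalized=normalized,
                                    prune_to_common=prune_to_common)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


class TreeSpaceEmbedding:
    """Classical (Torgerson) PCoA of a distance matrix.

    ``coordinates`` holds one row per tree over the retained positive-eigenvalue
    axes; ``variance_explained`` are eigenvalue fractions over the positive part.
    """

    def __init__(self, distances: pd.DataFrame, eigenvalues: np.ndarray,
                 coordinates: pd.DataFrame, n_negative: int):
        self.distances = distances
        self.eigenvalues = eigenvalues
        self.coordinates = coordinates
        self.n_negative = n_negative

    @property
    def variance_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return self.eigenvalues[: self.coordinates.shape[1]] / pos.sum()


def pcoa(distances, n_axes: int | None = None) -> TreeSpaceEmbedding:
    """Double-center -0.5 * J D^2 J, eigendecompose, scale by sqrt(eigenvalue).

    Negative eigenvalues (non-Euclidean input) are reported and truncated with
    a warning; axes are ordered by decreasing eigenvalue.
    """
    import warnings
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        labels = [f"tree{i + 1}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise TreeSpaceError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise TreeSpaceError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigval).max(initial=0.0)))
    n_negative = int((eigval < -tol).sum())
    if n_negative:
        warnings.warn(f"{n_negative} negative eigenvalue(s) truncated "
                      f"(non-Euclidean distances)", stacklevel=2)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    frame = pd.DataFrame(coords, index=labels,
                         columns=[f"axis{i + 1}" for i in range(coords.shape[1])])
    dist_frame = pd.DataFrame(D, index=labels, columns=labels)
    return TreeSpaceEmbedding(dist_frame, eigval, frame, n_negative)
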