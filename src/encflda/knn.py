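"""Weighted K-nearest-neighbor completion of the sparse association matrix.

The projected lncRNA-disease matrix is sparse: some lncRNAs touch no disease
and some diseases touch no lncRNA, which starves every later stage of signal.
Each disease column (and, in a parallel pass, each lncRNA row) is therefore
rebuilt as the cosine-similarity-weighted combination of its K most similar
peers, and the two passes are merged. By default only zero entries are filled,
so known signal is never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationMatrix
from .similarity import SimilarityMatrix, cosine_columns, cosine_rows

__all__ = ["KnnConfig", "knn_columns", "knn_rows", "complete"]


@dataclass
class KnnConfig:
    """Neighborhood-completion settings.

    Parameters
    ----------
    k : int
        Neighbor count; must satisfy ``1 <= k <= axis size - 1``.
    normalize_weights : bool
        Divide each weighted sum by the sum of the K similarities (when
        positive), keeping filled values on the scale of the originals.
        The raw unnormalized sum is available for fidelity runs.
    fill_only_zeros : bool
        Keep original nonzero entries, writing neighbor-derived values only
        into zero cells.
    combine : str
        How the row pass and column pass are merged: ``"mean"`` or ``"max"``.
    """

    k: int = 5
    normalize_weights: bool = True
    fill_only_zeros: bool = True
    combine: str = "mean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.combine not in ("mean", "max"):
            raise ValueError(f"combine must be 'mean' or 'max', got {self.combine!r}")

    def check_axis(self, size: int) -> None:
        if self.k >= size:
            raise ValueError(f"k={self.k} must be < axis size {size}")


def _weighted_neighbor_columns(values: np.ndarray, sim: np.ndarray,
                               cfg: KnnConfig) -> np.ndarray:
    """Rebuild each column of ``values`` from its top-k most similar columns.

    Self is excluded; ties in similarity break by entity index order.
    """
    n = values.shape[1]
    cfg.check_axis(n)
    out = np.zeros_like(values)
    for j in range(n):
        s = sim[:, j].copy()
        s[j] = -np.inf  # exclude self
        order = np.argsort(-s, kind="stable")[: cfg.k]
        w = sim[order, j]
        col = values[:, order] @ w
        if cfg.normalize_weights:
            total = w.sum()
            if total > 0:
                col = col / total
        out[:, j] = col
    if cfg.fill_only_zeros:
        out = np.where(values != 0, values, out)
    return out


def knn_columns(a: AssociationMatrix, cd: SimilarityMatrix,
                cfg: KnnConfig) -> AssociationMatrix:
    """Replace/fill each disease column with its weighted K-neighbor combination."""
    if cd.axis.names != a.cols.names:
        raise ValueError("similarity axis does not match matrix columns")
    return AssociationMatrix(a.rows, a.cols,
                             _weighted_neighbor_columns(a.values, cd.values, cfg))


def knn_rows(a: AssociationMatrix, cl: SimilarityMatrix,
             cfg: KnnConfig) -> AssociationMatrix:
    """Replace/fill each lncRNA row with its weighted K-neighbor combination."""
    if cl.axis.names != a.rows.names:
        raise ValueError("similarity axis does not match matrix rows")
    values = _weighted_neighbor_columns(a.values.T, cl.values, cfg).T
    return AssociationMatrix(a.rows, a.cols, values)


def complete(a: AssociationMatrix, cfg: KnnConfig) -> AssociationMatrix:
    """Densify ``a``: compute both similarity matrices, run the column pass and
    the row pass independently on the original matrix, and merge.

    Both passes read the original matrix (parallel, not sequential), so the
    result does not depend on pass order. With ``fill_only_zeros`` the original
    nonzero entries survive unchanged and sparsity can only decrease.
    """
    cfg.check_axis(len(a.cols))
    cfg.check_axis(len(a.rows))
    cd = cosine_columns(a)
    cl = cosine_rows(a)
    by_col = knn_columns(a, cd, cfg).values
    by_row = knn_rows(a, cl, cfg).values
    if cfg.combine == "mean":
        merged = (by_col + by_row) / 2.0
    else:
        merged = np.maximum(by_col, by_row)
    if cfg.fill_only_zeros:
        merged = np.where(a.values != 0, a.values, merged)
    return AssociationMatrix(a.rows, a.cols, merged)
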