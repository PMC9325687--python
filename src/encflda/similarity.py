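"""Cosine similarity between disease columns and lncRNA rows.

Similarity profiles are read straight off the (projected, possibly weighted)
lncRNA-disease association matrix: two diseases are similar when the same
lncRNAs connect to them, two lncRNAs when they connect to the same diseases.
An entity with an all-zero profile has, by convention, similarity 0 to
everything including itself, so downstream weighted sums stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationMatrix, EntityIndex

__all__ = ["SimilarityMatrix", "cosine_columns", "cosine_rows"]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity axis."""

    axis: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.axis)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")


def _cosine_gram(x: np.ndarray) -> np.ndarray:
    """Cosine similarity between the columns of ``x``; zero-norm columns -> 0."""
    norms = np.linalg.norm(x, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (x.T @ x) / np.outer(safe, safe)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    # exact symmetry and exact unit diagonal for nonzero profiles
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, np.where(zero, 0.0, 1.0))
    return sim


def cosine_columns(a: AssociationMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity between the columns (diseases) of ``a``."""
    if len(a.rows) < 1:
        raise ValueError("matrix must have at least one row")
    return SimilarityMatrix(a.cols, _cosine_gram(a.values))


def cosine_rows(a: AssociationMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity between the rows (lncRNAs) of ``a``."""
    if len(a.cols) < 1:
        raise ValueError("matrix must have at least one column")
    return SimilarityMatrix(a.rows, _cosine_gram(a.values.T))
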