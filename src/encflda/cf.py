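"""lncRNA-based neighborhood collaborative filtering over the refined matrix.

The factorization output (or, optionally, the KNN-completed matrix) plays the
role of a dense rating matrix psi. Each lncRNA's final score for a disease is
the similarity-weighted average of its neighbor lncRNAs' psi values for that
disease:

    score(i, j) = sum_{l in N(i)} Sim(i, l) * psi(l, j) / sum_{l in N(i)} Sim(i, l)

where Sim is row-profile cosine similarity and N(i) is the set of most similar
other lncRNAs (self excluded; all others by default). A zero denominator falls
back to psi(i, j) itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .associations import AssociationMatrix, EntityIndex
from .similarity import SimilarityMatrix, cosine_rows

__all__ = ["CfConfig", "ScoreMatrix", "cf_similarity", "cf_score", "ranked_list"]

_DENOM_EPS = 1e-12


@dataclass
class CfConfig:
    """Collaborative-filtering settings.

    ``neighborhood`` is either ``"all"`` (every other lncRNA) or a positive
    integer bounded by the number of lncRNAs minus one. ``source`` names which
    matrix plays psi: the factorization ``"reconstruction"`` (default) or the
    KNN-``"completed"`` matrix.
    """

    neighborhood: Union[int, str] = "all"
    source: str = "reconstruction"

    def __post_init__(self) -> None:
        if isinstance(self.neighborhood, str):
            if self.neighborhood != "all":
                raise ValueError(f"neighborhood must be 'all' or an int, got {self.neighborhood!r}")
        elif self.neighborhood < 1:
            raise ValueError("neighborhood must be a positive integer")
        if self.source not in ("reconstruction", "completed"):
            raise ValueError(f"source must be 'reconstruction' or 'completed', got {self.source!r}")

    def check_axis(self, n_l: int) -> None:
        if isinstance(self.neighborhood, int) and self.neighborhood > n_l - 1:
            raise ValueError(f"neighborhood={self.neighborhood} must be <= {n_l - 1}")


@dataclass
class ScoreMatrix:
    """Final association scores over lncRNA rows and disease columns."""

    rows: EntityIndex
    cols: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("score shape does not match indices")
        if not np.isfinite(self.values).all():
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.rows.names),
                            columns=list(self.cols.names))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def cf_similarity(psi: AssociationMatrix) -> SimilarityMatrix:
    """Cosine similarity between lncRNA row profiles of psi."""
    if len(psi.rows) < 2:
        raise ValueError("need at least two lncRNA rows")
    return cosine_rows(psi)


def cf_score(psi: AssociationMatrix | np.ndarray, sim: SimilarityMatrix,
             cfg: CfConfig) -> ScoreMatrix:
    """Similarity-weighted neighborhood average of psi rows."""
    if isinstance(psi, AssociationMatrix):
        rows, cols, p = psi.rows, psi.cols, psi.values
    else:
        raise TypeError("psi must be an AssociationMatrix")
    if sim.axis.names != rows.names:
        raise ValueError("similarity axis must match psi rows")
    n_l = len(rows)
    cfg.check_axis(n_l)

    s = sim.values.copy()
    np.fill_diagonal(s, 0.0)  # self excluded from every neighborhood
    if isinstance(cfg.neighborhood, int):
        keep = np.zeros_like(s, dtype=bool)
        for i in range(n_l):
            row = s[i].copy()
            row[i] = -np.inf
            order = np.argsort(-row, kind="stable")[: cfg.neighborhood]
            keep[i, order] = True
        s = np.where(keep, s, 0.0)

    denom = s.sum(axis=1)
    num = s @ p
    scores = np.empty_like(num)
    ok = np.abs(denom) > _DENOM_EPS
    scores[ok] = num[ok] / denom[ok, None]
    scores[~ok] = p[~ok]  # fallback: no usable neighbors
    return ScoreMatrix(rows, cols, scores)


def ranked_list(scores: ScoreMatrix) -> pd.DataFrame:
    """Per-disease ranking of lncRNAs by descending score.

    Columns: disease, lncRNA, score, rank (1 = best; ties keep index order).
    """
    records = []
    for j, disease in enumerate(scores.cols.names):
        col = scores.values[:, j]
        order = np.argsort(-col, kind="stable")
        for rank, i in enumerate(order, start=1):
            records.append((disease, scores.rows.names[i], col[i], rank))
    return pd.DataFrame(records, columns=["disease", "lncRNA", "score", "rank"])
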