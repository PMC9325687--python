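"""Edge-list input, labeled adjacency matrices, and the miRNA-mediated projection.

The prediction pipeline starts from two curated bipartite layers: lncRNA-miRNA
interactions and miRNA-disease associations. Both are read as two-column TSV
edge lists, turned into binary adjacency matrices over stable entity indices,
and multiplied through the shared miRNA axis to obtain the lncRNA-disease
association matrix whose entry (i, j) counts the miRNAs linking lncRNA i to
disease j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EntityIndex",
    "AssociationMatrix",
    "EdgeListError",
    "AlignmentError",
    "read_edge_list",
    "write_edge_list",
    "build_adjacency",
    "project",
    "build_network",
]


class EdgeListError(ValueError):
    """Malformed edge-list input or unknown entity names."""


class AlignmentError(ValueError):
    """Two matrices that must share an axis do not."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, immutable set of entity identifiers of one kind.

    Parameters
    ----------
    names : tuple of str
        Unique, non-empty identifiers. Position is stable for the lifetime
        of the index.
    kind : str
        One of ``"lncRNA"``, ``"miRNA"``, ``"disease"``.
    """

    names: tuple[str, ...]
    kind: str
    _pos: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if any(not n for n in self.names):
            raise ValueError("entity names must be non-empty")
        pos = {n: i for i, n in enumerate(self.names)}
        if len(pos) != len(self.names):
            dupes = [n for n in pos if self.names.count(n) > 1]
            raise ValueError(f"duplicate entity names: {dupes[:5]}")
        object.__setattr__(self, "_pos", pos)

    @classmethod
    def from_names(cls, names: Iterable[str], kind: str) -> "EntityIndex":
        """Build an index from names, sorted lexicographically and de-duplicated."""
        return cls(tuple(sorted(set(names))), kind)

    def position(self, name: str) -> int:
        return self._pos[name]

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self._pos


@dataclass
class AssociationMatrix:
    """Real-valued matrix over two labeled entity axes.

    Houses the raw adjacency layers (binary), the projected lncRNA-disease
    matrix (miRNA counts), and the KNN-completed weighted matrix. Values are
    always non-negative.
    """

    rows: EntityIndex
    cols: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match indices "
                f"({len(self.rows)}, {len(self.cols)})"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("association values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.rows.names),
                            columns=list(self.cols.names))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    def to_coo_tsv(self, path: str | Path) -> None:
        """Sparse text form: one (row_name, col_name, value) line per nonzero."""
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in np.argwhere(self.values != 0):
                fh.write(f"{self.rows.names[i]}\t{self.cols.names[j]}\t"
                         f"{self.values[i, j]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, row_kind: str, col_kind: str) -> "AssociationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        rows = EntityIndex(tuple(str(n) for n in df.index), row_kind)
        cols = EntityIndex(tuple(str(n) for n in df.columns), col_kind)
        return cls(rows, cols, df.to_numpy(dtype=float))


def read_edge_list(path: str | Path, row_kind: str = "", col_kind: str = "") -> list[tuple[str, str]]:
    """Read a two-column TSV edge list into de-duplicated ordered name pairs.

    Blank lines and lines starting with ``#`` are skipped. A third column
    (weight) is ignored with a warning. Lines with fewer than two tab-separated
    fields raise :class:`EdgeListError` naming the line number. An empty file
    yields an empty list.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    warned_extra = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields, got {line!r}"
                )
            if len(fields) > 2 and not warned_extra:
                logger.warning("%s: extra columns beyond the first two are ignored", path)
                warned_extra = True
            pair = (fields[0].strip(), fields[1].strip())
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


def write_edge_list(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write name pairs as a two-column TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def build_adjacency(
    pairs: Sequence[tuple[str, str]],
    rows: EntityIndex,
    cols: EntityIndex,
    on_unknown: str = "strict",
) -> AssociationMatrix:
    """Build a binary adjacency matrix: entry (i, j) = 1 iff the pair is present.

    ``on_unknown`` controls names missing from the indices: ``"strict"``
    (default) raises, ``"drop"`` skips the pair with a log message.
    """
    if on_unknown not in ("strict", "drop"):
        raise ValueError(f"unknown policy {on_unknown!r}")
    values = np.zeros((len(rows), len(cols)))
    for r, c in pairs:
        if r not in rows or c not in cols:
            missing = r if r not in rows else c
            if on_unknown == "strict":
                raise EdgeListError(f"unknown entity name {missing!r} in pair ({r}, {c})")
            logger.info("dropping pair (%s, %s): unknown name %r", r, c, missing)
            continue
        values[rows.position(r), cols.position(c)] = 1.0
    return AssociationMatrix(rows, cols, values)


def project(a_lm: AssociationMatrix, a_md: AssociationMatrix,
            binarize: bool = False) -> AssociationMatrix:
    """Project the two bipartite layers into the lncRNA-disease matrix.

    Computes the matrix product A_LM @ A_MD over the shared miRNA axis, so
    entry (i, j) counts the miRNAs m with both A_LM(i, m) = 1 and
    A_MD(m, j) = 1. Counts are kept by default; ``binarize`` clips the result
    to 0/1.
    """
    if a_lm.cols.names != a_md.rows.names:
        sym = set(a_lm.cols.names) ^ set(a_md.rows.names)
        raise AlignmentError(
            "miRNA axes do not match; symmetric difference of names: "
            f"{sorted(sym)[:10]}{'...' if len(sym) > 10 else ''}"
        )
    values = a_lm.values @ a_md.values
    if binarize:
        values = (values > 0).astype(float)
    return AssociationMatrix(a_lm.rows, a_md.cols, values)


def build_network(
    lm_pairs: Sequence[tuple[str, str]],
    md_pairs: Sequence[tuple[str, str]],
    strict: bool = False,
) -> tuple[AssociationMatrix, AssociationMatrix]:
    """Build aligned A_LM and A_MD adjacency matrices from the two edge lists.

    Entity indices come from the union of names in the inputs, sorted
    lexicographically. The shared miRNA index is the union across both layers;
    miRNAs seen in only one layer get all-zero rows/columns in the other
    (logged), unless ``strict`` is set, in which case the mismatch errors.
    """
    lnc = EntityIndex.from_names((l for l, _ in lm_pairs), "lncRNA")
    mir_lm = {m for _, m in lm_pairs}
    mir_md = {m for m, _ in md_pairs}
    only_one_side = mir_lm ^ mir_md
    if only_one_side:
        if strict:
            raise AlignmentError(
                f"miRNAs present in only one layer: {sorted(only_one_side)[:10]}"
            )
        logger.info("%d miRNAs present in only one layer; kept with zero profiles",
                    len(only_one_side))
    mirna = EntityIndex.from_names(mir_lm | mir_md, "miRNA")
    disease = EntityIndex.from_names((d for _, d in md_pairs), "disease")
    a_lm = build_adjacency(lm_pairs, lnc, mirna)
    a_md = build_adjacency(md_pairs, mirna, disease)
    return a_lm, a_md
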