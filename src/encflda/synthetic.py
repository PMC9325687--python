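"""Reproducible synthetic lncRNA-miRNA-disease networks with planted structure.

Each entity (lncRNA, miRNA, disease) is assigned one of ``rank`` latent
clusters; edges in the two bipartite layers are sampled with elevated
probability between same-cluster pairs (a stochastic block model with a fixed
5:1 within:between odds ratio, calibrated analytically so the realized edge
density matches the target), then each cell is flipped with a small noise
probability. The noise-free lncRNA-disease cluster-match indicator is the
planted truth, and the emitted gold-standard pairs are sampled from its
positive cells — mimicking a sparse curated association database sitting on
top of real shared-miRNA structure.

This emulates the *shape* of the curated inputs (binary edge lists joined
through a shared miRNA layer), not their degree distributions or identifier
vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationMatrix, EntityIndex

__all__ = ["SynthConfig", "SyntheticNetwork", "generate"]

_WITHIN_BETWEEN_ODDS = 5.0


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's standard desk-scale
    study conditions.

    Parameters
    ----------
    n_l, n_m, n_d : int
        Entity counts for lncRNAs, miRNAs, diseases.
    rank : int
        Number of planted latent clusters; at most min(n_l, n_m, n_d).
    density_lm, density_md : float
        Target edge densities of the two layers, in (0, 1).
    noise : float
        Edge-flip (drop) probability in [0, 0.5): each sampled edge is removed
        with this probability, emulating incomplete curation.
    n_gold : int
        Number of gold lncRNA-disease pairs sampled from truth positives.
    seed : int
        Seed for all randomness.
    """

    n_l: int = 40
    n_m: int = 20
    n_d: int = 15
    rank: int = 3
    density_lm: float = 0.1
    density_md: float = 0.1
    noise: float = 0.05
    n_gold: int = 50
    seed: int = 7

    def __post_init__(self) -> None:
        if min(self.n_l, self.n_m, self.n_d) < 1:
            raise ValueError("entity counts must be positive")
        if not 1 <= self.rank <= min(self.n_l, self.n_m, self.n_d):
            raise ValueError("rank must be in [1, min(n_l, n_m, n_d)]")
        for name, dens in (("density_lm", self.density_lm), ("density_md", self.density_md)):
            if not 0.0 < dens < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.n_gold < 1:
            raise ValueError("n_gold must be positive")


@dataclass
class SyntheticNetwork:
    """Generated edge lists, gold standard, and the planted truth matrix."""

    lm_pairs: list[tuple[str, str]]
    md_pairs: list[tuple[str, str]]
    gold_pairs: list[tuple[str, str]]
    truth: AssociationMatrix


def _names(prefix: str, n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(1, n + 1))


def _block_probs(match_fraction: float, density: float) -> tuple[float, float]:
    """Solve within/between edge probabilities for a target density at fixed
    5:1 within:between odds. Errors when the combination is infeasible."""
    p_between = density / (_WITHIN_BETWEEN_ODDS * match_fraction + (1.0 - match_fraction))
    p_within = _WITHIN_BETWEEN_ODDS * p_between
    if p_within > 1.0:
        raise ValueError(
            f"infeasible density/cluster combination: within-cluster edge "
            f"probability {p_within:.3f} exceeds 1"
        )
    return p_within, p_between


def _sample_layer(c_rows: np.ndarray, c_cols: np.ndarray, density: float,
                  noise: float, rng: np.random.Generator) -> np.ndarray:
    match = c_rows[:, None] == c_cols[None, :]
    p_w, p_b = _block_probs(float(match.mean()), density)
    adj = rng.random(match.shape) < np.where(match, p_w, p_b)
    if noise > 0:
        # noise = missed curation: each sampled edge dropped with this probability
        adj &= rng.random(match.shape) >= noise
    return adj.astype(float)


def _ensure_rows_nonempty(adj: np.ndarray, c_rows: np.ndarray, c_cols: np.ndarray,
                          rng: np.random.Generator) -> None:
    """Give every all-zero row one edge, preferring a same-cluster column.

    Curated databases only list entities with at least one record, so every
    named entity must appear in its layer's edge list.
    """
    for i in np.flatnonzero(adj.sum(axis=1) == 0):
        candidates = np.flatnonzero(c_cols == c_rows[i])
        if len(candidates) == 0:
            candidates = np.arange(adj.shape[1])
        adj[i, rng.choice(candidates)] = 1.0


def _pairs(adj: np.ndarray, row_names: tuple[str, ...],
           col_names: tuple[str, ...]) -> list[tuple[str, str]]:
    return [(row_names[i], col_names[j]) for i, j in np.argwhere(adj > 0)]


def generate(cfg: SynthConfig) -> SyntheticNetwork:
    """Draw a three-layer network with planted cluster structure.

    All outputs are reproducible from ``cfg.seed``. Gold pairs are always a
    subset of truth positives (the truth matrix is noise-free by definition).
    """
    rng = np.random.default_rng(cfg.seed)
    c_l = rng.integers(cfg.rank, size=cfg.n_l)
    c_m = rng.integers(cfg.rank, size=cfg.n_m)
    c_d = rng.integers(cfg.rank, size=cfg.n_d)

    lnc = EntityIndex(_names("L", cfg.n_l), "lncRNA")
    mir = EntityIndex(_names("M", cfg.n_m), "miRNA")
    dis = EntityIndex(_names("D", cfg.n_d), "disease")

    a_lm = _sample_layer(c_l, c_m, cfg.density_lm, cfg.noise, rng)
    a_md = _sample_layer(c_m, c_d, cfg.density_md, cfg.noise, rng)
    _ensure_rows_nonempty(a_lm, c_l, c_m, rng)
    _ensure_rows_nonempty(a_md.T, c_d, c_m, rng)

    truth_values = (c_l[:, None] == c_d[None, :]).astype(float)
    truth = AssociationMatrix(lnc, dis, truth_values)

    positives = np.argwhere(truth_values > 0)
    if cfg.n_gold > len(positives):
        raise ValueError(
            f"n_gold={cfg.n_gold} exceeds the {len(positives)} truth-positive cells"
        )
    chosen = positives[rng.choice(len(positives), size=cfg.n_gold, replace=False)]
    gold = [(lnc.names[i], dis.names[j]) for i, j in sorted(map(tuple, chosen))]

    return SyntheticNetwork(
        lm_pairs=_pairs(a_lm, lnc.names, mir.names),
        md_pairs=_pairs(a_md, mir.names, dis.names),
        gold_pairs=gold,
        truth=truth,
    )
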