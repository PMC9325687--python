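"""Leave-one-out cross-validation and threshold-sweep ROC / precision-recall.

Known lncRNA-disease associations form the gold standard; every other pair is
treated as a (putative) negative, the no-negative-sample convention standard
in this literature. Each gold pair in turn is the single held-out test case:
its prediction score and rank among candidate pairs are recorded, and the
pooled held-out scores versus never-known-pair scores yield ROC/AUC and
PR/AUPR by threshold sweep (trapezoidal integration, tied scores grouped into
one threshold step, so AUC equals the normalized Mann-Whitney statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .associations import AssociationMatrix, build_network
from .cf import ScoreMatrix

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "confusion_at_threshold",
    "roc_auc",
    "pr_aupr",
    "loocv",
    "mann_whitney_auc",
    "permutation_pvalue",
    "plot_curves",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalResult:
    """ROC and PR curves with their areas, plus per-fold LOOCV records."""

    roc_points: list[tuple[float, float]]  # (FPR, TPR)
    pr_points: list[tuple[float, float]]   # (recall, precision)
    auc: float
    aupr: float
    per_fold_scores: list[tuple[str, str, float, int]] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.per_fold_scores)


def confusion_at_threshold(scores: ScoreMatrix | np.ndarray,
                           gold: AssociationMatrix | np.ndarray,
                           t: float) -> ConfusionCounts:
    """Count TP/FP/TN/FN with pairs predicted positive iff score >= t."""
    s = scores.values if hasattr(scores, "values") else np.asarray(scores, float)
    g = gold.values if hasattr(gold, "values") else np.asarray(gold, float)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {g.shape}")
    pred = s >= t
    pos = g != 0
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _validate_labels(labels: np.ndarray, need_both: bool = True) -> None:
    if need_both and (labels.sum() == 0 or labels.sum() == len(labels)):
        raise ValueError("need at least one positive and one negative label")
    if labels.sum() == 0:
        raise ValueError("need at least one positive label")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """ROC curve points and trapezoidal AUC from a full threshold sweep.

    Tied scores share one threshold step. Returns (points, auc) with points
    ordered from (0, 0) to (1, 1) by non-decreasing FPR.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _validate_labels(y)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def pr_aupr(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall curve points and AUPR by trapezoid over recall."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _validate_labels(y, need_both=False)
    precision, recall, _ = precision_recall_curve(y, s)
    # one value per recall level: the best precision achieved there
    # (upper envelope of the threshold-sweep sawtooth)
    envelope: dict[float, float] = {}
    for r, p in zip(recall.tolist(), precision.tolist()):
        envelope[r] = max(envelope.get(r, 0.0), p)
    rs = sorted(envelope)
    ps = [envelope[r] for r in rs]
    aupr = float(np.trapezoid(ps, rs))
    return list(zip(rs, ps)), aupr


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U (ties credited 0.5), via midranks."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def permutation_pvalue(pos: np.ndarray, neg: np.ndarray, n_perm: int = 999,
                       seed: int = 0) -> float:
    """One-sided permutation test of AUC > 0.5 by shuffling pool membership."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    observed = mann_whitney_auc(pos, neg)
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    n_pos, n = len(pos), len(pooled)
    offset = n_pos * (n_pos + 1) / 2.0
    denom = n_pos * (n - n_pos)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_pos, replace=False)
        perm_auc = (ranks[idx].sum() - offset) / denom
        if perm_auc >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _held_out_rank(score: float, candidate_scores: np.ndarray) -> int:
    """Competition rank of the held-out score among candidates plus itself."""
    return int(1 + np.sum(candidate_scores > score))


def loocv(
    lm_pairs: Sequence[tuple[str, str]],
    md_pairs: Sequence[tuple[str, str]],
    gold_pairs: Sequence[tuple[str, str]],
    cfg: "PipelineConfig",
    scorer: Optional[Callable[..., ScoreMatrix]] = None,
) -> EvalResult:
    """Leave-one-out cross-validation over the known gold associations.

    For each gold pair the pipeline is run with that pair held out, its score
    and rank among candidate (never-known) pairs recorded, and the pooled
    held-out scores against candidate scores give AUC/AUPR.

    Two hold-out readings are supported. By default the gold standard never
    enters the association matrix (it is built purely from the miRNA
    projection), so holding a pair out only removes it from the positive set
    and a single pipeline run scores every fold. With
    ``cfg.include_gold_in_matrix`` the gold pairs are written into the matrix
    and the held-out cell is zeroed before each fold's pipeline run.

    ``scorer`` optionally replaces the pipeline: a callable taking
    (A_LM, A_MD, cfg) and returning a ScoreMatrix.
    """
    from .pipeline import PipelineConfig, run_pipeline  # deferred: avoids cycle

    assert isinstance(cfg, PipelineConfig)
    if not gold_pairs:
        raise ValueError("gold set is empty")
    a_lm, a_md = build_network(lm_pairs, md_pairs)
    lnc, dis = a_lm.rows, a_md.cols
    for l, d in gold_pairs:
        if l not in lnc or d not in dis:
            missing = l if l not in lnc else d
            raise ValueError(f"gold pair ({l}, {d}) references unknown entity {missing!r}")

    score_fn = scorer if scorer is not None else (
        lambda lm, md, c, **kw: run_pipeline(lm, md, c, **kw).scores)
    gold_idx = [(lnc.position(l), dis.position(d)) for l, d in gold_pairs]
    gold_mask = np.zeros((len(lnc), len(dis)), dtype=bool)
    for i, j in gold_idx:
        gold_mask[i, j] = True

    per_fold: list[tuple[str, str, float, int]] = []
    if not cfg.include_gold_in_matrix:
        # matrix does not depend on the gold set: one run scores all folds
        scores = score_fn(a_lm, a_md, cfg).values
        neg_scores = scores[~gold_mask]
        for (l, d), (i, j) in zip(gold_pairs, gold_idx):
            per_fold.append((l, d, float(scores[i, j]), _held_out_rank(scores[i, j], neg_scores)))
        pos_scores = np.array([s for _, _, s, _ in per_fold])
    else:
        base = score_fn(a_lm, a_md, cfg, gold_mask=gold_mask).values
        neg_scores = base[~gold_mask]
        for (l, d), (i, j) in zip(gold_pairs, gold_idx):
            fold_mask = gold_mask.copy()
            fold_mask[i, j] = False
            # held-out cell is zeroed entirely; completion must recover it
            fold = score_fn(a_lm, a_md, cfg, gold_mask=fold_mask,
                            zero_cells=[(i, j)]).values
            per_fold.append((l, d, float(fold[i, j]), _held_out_rank(fold[i, j], neg_scores)))
        pos_scores = np.array([s for _, _, s, _ in per_fold])

    pooled = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores), int), np.zeros(len(neg_scores), int)])
    roc_points, auc_val = roc_auc(pooled, labels)
    pr_points, aupr_val = pr_aupr(pooled, labels)
    return EvalResult(roc_points, pr_points, auc_val, aupr_val, per_fold)


def plot_curves(result: EvalResult, path: str) -> None:
    """Write a side-by-side ROC / PR figure as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    fpr, tpr = zip(*result.roc_points)
    ax1.plot(fpr, tpr, label=f"AUC = {result.auc:.4f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set_xlabel("FPR"), ax1.set_ylabel("TPR"), ax1.set_title("ROC"), ax1.legend()
    rec, prec = zip(*result.pr_points)
    ax2.plot(rec, prec, label=f"AUPR = {result.aupr:.4f}")
    ax2.set_xlabel("recall"), ax2.set_ylabel("precision"), ax2.set_title("PR"), ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
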