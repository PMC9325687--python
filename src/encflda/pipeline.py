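"""Pipeline orchestration: project -> KNN completion -> factorization -> CF.

Each stage can be toggled off for ablation runs, in which case its input
matrix passes through unchanged. All randomness flows from the configured
seeds, and every run writes a manifest of the fully resolved parameters so
it can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .associations import AssociationMatrix, build_network, project, read_edge_list
from .cf import CfConfig, ScoreMatrix, cf_score, cf_similarity, ranked_list
from .enmf import EnmfConfig, factorize, reconstruct
from .knn import KnnConfig, complete

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_predict", "run_evaluate", "run_sweep"]


@dataclass
class PipelineConfig:
    """Aggregate configuration for a full prediction run."""

    knn: KnnConfig = field(default_factory=KnnConfig)
    mf: EnmfConfig = field(default_factory=EnmfConfig)
    cf: CfConfig = field(default_factory=CfConfig)
    enable_knn: bool = True
    enable_mf: bool = True
    enable_cf: bool = True
    binarize_projection: bool = False
    include_gold_in_matrix: bool = False

    def __post_init__(self) -> None:
        if not (self.enable_knn or self.enable_mf or self.enable_cf):
            # projection alone is still a valid (fully ablated) run
            logger.info("all refinement stages disabled; scores = raw projection")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        knn = KnnConfig(**d.pop("knn", {}))
        mf = EnmfConfig(**d.pop("mf", {}))
        cf = CfConfig(**d.pop("cf", {}))
        return cls(knn=knn, mf=mf, cf=cf, **d)


@dataclass
class PipelineResult:
    """Final scores plus the intermediate matrices of each executed stage."""

    scores: ScoreMatrix
    projected: AssociationMatrix
    completed: AssociationMatrix
    reconstruction: Optional[AssociationMatrix]
    mf_trace: list[tuple[int, float]]


def _clip_nonneg(values: np.ndarray) -> np.ndarray:
    return np.maximum(values, 0.0)


def run_pipeline(a_lm: AssociationMatrix, a_md: AssociationMatrix,
                 cfg: PipelineConfig,
                 gold_mask: Optional[np.ndarray] = None,
                 zero_cells: Optional[Sequence[tuple[int, int]]] = None) -> PipelineResult:
    """Execute the enabled stages in order on in-memory adjacency matrices.

    ``gold_mask`` optionally marks known lncRNA-disease cells to write into
    the projected matrix (used by the gold-in-matrix cross-validation mode);
    marked cells are raised to at least 1. ``zero_cells`` are (row, col)
    positions forced to zero after the projection — the held-out associations
    of a cross-validation fold, which the completion stages must recover.
    """
    t0 = time.perf_counter()
    a_ld = project(a_lm, a_md, binarize=cfg.binarize_projection)
    if gold_mask is not None or zero_cells:
        values = a_ld.values.copy()
        if gold_mask is not None:
            values[gold_mask] = np.maximum(values[gold_mask], 1.0)
        for i, j in zero_cells or ():
            values[i, j] = 0.0
        a_ld = AssociationMatrix(a_ld.rows, a_ld.cols, values)
    logger.info("projection: %s in %.3fs", a_ld.shape, time.perf_counter() - t0)

    completed = complete(a_ld, cfg.knn) if cfg.enable_knn else a_ld

    recon: Optional[AssociationMatrix] = None
    trace: list[tuple[int, float]] = []
    if cfg.enable_mf:
        t0 = time.perf_counter()
        result = factorize(completed, cfg.mf)
        trace = result.trace
        # reconstruction can dip slightly negative; association semantics clip it
        recon = AssociationMatrix(completed.rows, completed.cols,
                                  _clip_nonneg(reconstruct(result.factors)))
        logger.info("factorization: %d iters, loss %.6g in %.3fs",
                    len(trace) - 1, result.final_loss, time.perf_counter() - t0)

    current = recon if recon is not None else completed
    if cfg.enable_cf:
        source = completed if (cfg.cf.source == "completed" or recon is None) else recon
        sim = cf_similarity(source)
        scores = cf_score(source, sim, cfg.cf)
    else:
        scores = ScoreMatrix(current.rows, current.cols, current.values)
    return PipelineResult(scores=scores, projected=a_ld, completed=completed,
                          reconstruction=recon, mf_trace=trace)


def _write_manifest(cfg: PipelineConfig, outdir: Path, extra: dict) -> None:
    manifest = {"config": cfg.to_dict(), **extra}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_predict(cfg: PipelineConfig, lm_path: str | Path, md_path: str | Path,
                outdir: str | Path) -> ScoreMatrix:
    """Run the pipeline on edge-list files; write scores, ranked lists, manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lm_pairs = read_edge_list(lm_path)
    md_pairs = read_edge_list(md_path)
    a_lm, a_md = build_network(lm_pairs, md_pairs)
    result = run_pipeline(a_lm, a_md, cfg)
    result.scores.to_tsv(out / "scores.tsv")
    ranked_list(result.scores).to_csv(out / "ranked.tsv", sep="\t", index=False,
                                      float_format="%.10g")
    if result.mf_trace:
        with open(out / "mf_trace.tsv", "w") as fh:
            fh.write("iteration\tloss\n")
            for it, lv in result.mf_trace:
                fh.write(f"{it}\t{lv:.10g}\n")
    _write_manifest(cfg, out, {"inputs": {"lm": str(lm_path), "md": str(md_path)}})
    return result.scores


def run_evaluate(cfg: PipelineConfig, lm_path: str | Path, md_path: str | Path,
                 gold_path: str | Path, outdir: str | Path,
                 plot: bool = False) -> "EvalResult":
    """LOOCV over a gold-standard edge list; write metrics JSON and curves."""
    from .evaluation import loocv, plot_curves

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gold_file = Path(gold_path)
    if not gold_file.exists():
        raise FileNotFoundError(f"gold-standard edge list not found: {gold_file}")
    lm_pairs = read_edge_list(lm_path)
    md_pairs = read_edge_list(md_path)
    gold_pairs = read_edge_list(gold_file)
    result = loocv(lm_pairs, md_pairs, gold_pairs, cfg)
    (out / "metrics.json").write_text(json.dumps(
        {"auc": result.auc, "aupr": result.aupr, "n_folds": result.n_folds},
        indent=2))
    with open(out / "roc.tsv", "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in result.roc_points:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
    with open(out / "pr.tsv", "w") as fh:
        fh.write("recall\tprecision\n")
        for rec, prec in result.pr_points:
            fh.write(f"{rec:.10g}\t{prec:.10g}\n")
    if plot:
        plot_curves(result, str(out / "curves.png"))
    _write_manifest(cfg, out, {"inputs": {"lm": str(lm_path), "md": str(md_path),
                                          "gold": str(gold_file)}})
    return result


_SWEEPABLE = {
    "mf-alpha": ("mf", "alpha", float),
    "mf-lambda": ("mf", "lam", float),
    "mf-k": ("mf", "k", int),
    "mf-lr": ("mf", "learning_rate", float),
    "knn-k": ("knn", "k", int),
}


def run_sweep(cfg: PipelineConfig, param: str, values: Sequence[float],
              lm_path: str | Path, md_path: str | Path, gold_path: str | Path,
              outdir: str | Path) -> list[tuple[float, float, float]]:
    """Evaluate once per parameter value; write a (value, auc, aupr) table."""
    from .evaluation import loocv

    if param not in _SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {param!r}; one of {sorted(_SWEEPABLE)}")
    if not values:
        raise ValueError("empty sweep value list")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lm_pairs = read_edge_list(lm_path)
    md_pairs = read_edge_list(md_path)
    gold_pairs = read_edge_list(gold_path)
    section, attr, cast = _SWEEPABLE[param]
    rows: list[tuple[float, float, float]] = []
    for v in values:
        d = cfg.to_dict()
        d[section][attr] = cast(v)
        res = loocv(lm_pairs, md_pairs, gold_pairs, PipelineConfig.from_dict(d))
        rows.append((float(v), res.auc, res.aupr))
        logger.info("sweep %s=%s: auc=%.4f aupr=%.4f", param, v, res.auc, res.aupr)
    with open(out / f"sweep_{param.replace('-', '_')}.tsv", "w") as fh:
        fh.write(f"{param}\tauc\taupr\n")
        for v, a, p in rows:
            fh.write(f"{v:.10g}\t{a:.10g}\t{p:.10g}\n")
    return rows
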