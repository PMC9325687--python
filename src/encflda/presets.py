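"""Canonical configurations for the desk-scale synthetic study.

The full method was designed around curated databases with on the order of a
thousand lncRNAs and hundreds of diseases. The desk-scale study runs the same
pipeline on a small planted-structure network (40 lncRNAs x 20 miRNAs x 15
diseases, 3 latent clusters) so that leave-one-out cross-validation completes
in seconds. Three settings are resized for that scale and fixed here, once:

* factorization latent dimension k = 10 (the matrix has only 15 columns;
  the large-scale default of 50 would be over-parameterized),
* collaborative-filtering neighborhood of 10 lncRNAs (with only 39 possible
  neighbors, the method's unbounded neighbor sum degenerates toward the
  per-disease column mean, a known small-sample pathology of neighborhood
  CF; a bounded neighborhood is the standard remedy),
* cross-validation embeds the gold standard in the association matrix and
  zeroes the held-out cell per fold, so each fold genuinely tests whether
  the completion stages recover a removed association.
"""

from __future__ import annotations

from .cf import CfConfig
from .enmf import EnmfConfig
from .knn import KnnConfig
from .pipeline import PipelineConfig
from .synthetic import SynthConfig

__all__ = ["desk_synth_config", "desk_pipeline_config", "desk_ablation_config"]


def desk_synth_config(seed: int = 7) -> SynthConfig:
    """The desk-scale synthetic study conditions (only the seed varies)."""
    return SynthConfig(seed=seed)


def desk_pipeline_config(seed: int = 1) -> PipelineConfig:
    """Full pipeline sized for the desk-scale matrix."""
    return PipelineConfig(
        knn=KnnConfig(k=5),
        mf=EnmfConfig(k=10, learning_rate=3e-3, max_iters=800, tol=1e-8,
                      seed=seed),
        cf=CfConfig(neighborhood=10),
        include_gold_in_matrix=True,
    )


def desk_ablation_config() -> PipelineConfig:
    """Projection-only arm: every refinement stage disabled."""
    return PipelineConfig(enable_knn=False, enable_mf=False, enable_cf=False,
                          include_gold_in_matrix=True)
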