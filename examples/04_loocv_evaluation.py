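"""Leave-one-out cross-validation of the full pipeline on synthetic data.

Each known (gold) lncRNA-disease association is held out in turn: it is
removed from the association matrix, the pipeline re-runs, and the held-out
pair's score is pooled against all never-known pairs. An AUC near 1 means
held-out associations are recovered ahead of random pairs; 0.5 means chance.
The projection-only arm shows what the completion stages add.
"""

import numpy as np

from encflda import build_network, generate, loocv, permutation_pvalue, run_pipeline
from encflda.presets import (desk_ablation_config, desk_pipeline_config,
                             desk_synth_config)

net = generate(desk_synth_config(seed=7))
print(f"study network: {len(net.lm_pairs)} lncRNA-miRNA edges, "
      f"{len(net.md_pairs)} miRNA-disease edges, {len(net.gold_pairs)} gold pairs")

full_cfg = desk_pipeline_config(seed=1)
full = loocv(net.lm_pairs, net.md_pairs, net.gold_pairs, full_cfg)
ablation = loocv(net.lm_pairs, net.md_pairs, net.gold_pairs, desk_ablation_config())

a_lm, a_md = build_network(net.lm_pairs, net.md_pairs)
gold_mask = np.zeros((len(a_lm.rows), len(a_md.cols)), bool)
for l, d in net.gold_pairs:
    gold_mask[a_lm.rows.position(l), a_md.cols.position(d)] = True
base = run_pipeline(a_lm, a_md, full_cfg, gold_mask=gold_mask).scores.values
pos = np.array([s for _, _, s, _ in full.per_fold_scores])
pval = permutation_pvalue(pos, base[~gold_mask], n_perm=1999, seed=0)

print(f"\nfull pipeline      : AUC {full.auc:.3f}  AUPR {full.aupr:.3f} "
      f"(permutation p = {pval:.4f})")
print(f"projection only    : AUC {ablation.auc:.3f}  AUPR {ablation.aupr:.3f}")
print("\nThe full pipeline recovers held-out associations well above chance; "
      "the raw projection cannot, because a removed association leaves no "
      "trace in its own cell.")
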