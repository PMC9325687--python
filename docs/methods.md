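# Methods

## Problem setting

Given two curated bipartite layers — lncRNA–miRNA interactions and
miRNA–disease associations — the task is to score every lncRNA–disease pair
for likely association. Direct lncRNA–disease annotations are used only as a
gold standard for evaluation, never as a model input (except in the
embedded-gold cross-validation mode described below).

## Pipeline

### Projection

`A_LD = A_LM · A_MD` over a shared miRNA index. The miRNA index is the union
of the miRNAs named in either layer (sorted lexicographically, as are all
entity indices); miRNAs present in only one layer contribute zero rows or
columns and are logged. The product is kept as integer shared-neighbour
counts rather than re-binarised: the similarity and completion stages operate
on weighted profiles, and collapsing counts to 0/1 would discard the
multiplicity of molecular routes between a pair. A `binarize` flag restores
0/1 semantics.

### Cosine similarity

Disease–disease similarity `CD` is the cosine between columns of `A_LD`;
lncRNA–lncRNA similarity `CL` the cosine between rows. An all-zero profile
has similarity 0 to everything, including itself — the alternative (NaN or 1)
would poison downstream weighted sums. Similarities are exactly symmetric and
the diagonal is exactly 1 for nonzero profiles.

### Weighted KNN completion

Each disease column is replaced by the similarity-weighted combination of its
K most similar other columns (ties broken by index order, self excluded);
likewise each lncRNA row. Both passes read the *original* matrix and are
merged (mean by default, max optional), so the result does not depend on pass
order. Defaults, each exposed as a flag:

| parameter | default | why |
|---|---|---|
| K | 5 | conventional small neighbourhood; the stage is on/off-ablatable |
| normalize_weights | true | unnormalised sums scale with K and destabilise the factorization; the literal unnormalised sum remains available |
| fill_only_zeros | true | the stage exists to repair entities with empty profiles, not to overwrite known signal |
| combine | mean | symmetric treatment of the two passes |

### Elastic-net matrix factorization

ψ ≈ U·Vᵀ, U ∈ R^{n_l×k}, V ∈ R^{n_d×k}, minimising squared error over the
observed (nonzero) cells κ plus the elastic-net penalty
λ(α·L1 + (1−α)·L2) on all factor entries. Training is full-batch gradient
descent with the L1 subgradient sgn(·) (sgn(0)=0) and step size η;
a per-observed-cell stochastic variant (`sgd`) is provided but the
deterministic full-batch form is the default because it is reproducible and
testable. Factors are initialised i.i.d. uniform on [0, 1/√k] from the
config seed; the factors with the lowest loss seen along the trajectory are
returned together with the full (iteration, loss) trace.

Defaults: α = 0.3, λ = 0.01, k = 50, η = 1e-3, 200 iterations, stop when the
loss change drops below 1e-6. k = 50 is sized for matrices with hundreds of
columns; small problems should set k near their expected rank (the
desk-scale preset uses k = 10 for a 40×15 matrix). Gradient correctness is
verified against central finite differences at differentiable points, and
the α = 0 / α = 1 limits against separately coded ridge and lasso
objectives. Divergence (non-finite loss) raises an error suggesting a
smaller η rather than returning garbage.

Factors are unconstrained reals; the reconstruction U·Vᵀ is clipped at zero
before re-entering association-matrix semantics, since a (small) negative
predicted association count is meaningless.

### Collaborative filtering

`score(i, j) = Σ_{l∈N(i)} Sim(i,l)·ψ̂(l,j) / Σ_{l∈N(i)} Sim(i,l)`, where
`Sim` is the row-cosine of the reconstruction (or, optionally, of the
KNN-completed matrix) and `N(i)` is the neighbourhood of most similar other
lncRNAs — all of them by default, a bounded number optionally. Self is
excluded: including it would make the stage a near-identity. A zero
denominator falls back to ψ̂(i, j). Note the stage scores a pair purely from
*other* lncRNAs' profiles; its value depends on the neighbourhood carrying
real signal.

## Evaluation

### ROC / PR

Threshold-sweep curves with tied scores grouped into one step; AUC by
trapezoid, which on these grouped sweeps equals the midrank Mann–Whitney
statistic (verified against a pairwise-comparison oracle to 1e-12). AUPR is
the trapezoid over recall of the upper envelope of the precision–recall
sawtooth (best precision per achieved recall level). Caveat: with heavy score
ties the PR curve degenerates to very few points and trapezoidal AUPR can be
substantially inflated (e.g. a scorer giving all positives the identical
lowest score yields a two-point curve from (0,1) to (1, prevalence) and an
AUPR near 0.5); AUPR is therefore only meaningful for scorers producing
continuous scores. AUC is unaffected.

### Leave-one-out cross-validation

Every gold pair in turn is the single test case. Two readings of "held out"
are shipped, because the association matrix is built from the miRNA
projection, not from the gold standard:

* **metric-only** (default): the matrix never contains gold information, so
  removing a pair changes nothing upstream; one pipeline run scores all
  folds, and the held-out pair is simply excluded from the positive set.
  This measures how well the projection-derived signal ranks known
  associations.
* **embedded-gold** (`include_gold_in_matrix`): gold cells are raised to at
  least 1 in the projected matrix; for each fold the held-out cell is zeroed
  entirely (including its projection count) before the pipeline runs. This
  is the reading in which leave-one-out actually tests matrix completion:
  the pipeline must recover a deleted association from its neighbourhood and
  low-rank structure. Negative-pair scores are pooled from a single
  reference run with the full gold set embedded; per-fold negative pooling
  would cost folds × pairs memory at realistic scale for no change in the
  ranking being tested.

Negatives are all pairs not in the gold standard (no negative sampling).
AUC significance is assessed by a one-sided permutation test (1999
permutations of pool membership, midrank statistic).

## Synthetic study networks

The generator plants `rank` latent clusters over all three entity sets and
samples each bipartite layer as a stochastic block model with a fixed 5:1
within:between odds ratio, calibrated analytically so the realized edge
density matches the target. Noise removes each sampled edge with the given
probability, emulating incomplete curation — the dominant error mode of
curated interaction databases, which rarely contain false positives. Every
lncRNA keeps at least one lncRNA–miRNA edge and every disease at least one
miRNA–disease edge (databases only name entities with at least one record).
The noise-free lncRNA–disease cluster-match indicator is the planted truth;
gold pairs are sampled uniformly from its positive cells.

What this emulates: binary edge lists joined through a shared miRNA layer,
with low-rank association structure and a sparse curated gold standard.
What it does not: real degree distributions (curated databases are heavily
hub-dominated), identifier vocabularies, or biased curation (real gold
standards oversample well-studied diseases). Passing tests therefore show
the pipeline recovers planted low-rank structure through the miRNA layer —
not that it attains any particular performance on real curated data.

## Desk-scale study configuration

The standard small study (`encflda.presets`) uses 40 lncRNAs × 20 miRNAs ×
15 diseases, 3 clusters, layer densities 0.1, noise 0.05, 50 gold pairs.
Three settings are resized for this scale, fixed once in the preset:

* factorization k = 10 (a 50-dimensional latent space would exceed the
  matrix's column count);
* CF neighbourhood = 10 of the 39 possible neighbours — with so few lncRNAs
  the unbounded neighbour sum degenerates toward the per-disease column
  mean, a known small-sample pathology of neighbourhood CF; bounding the
  neighbourhood is the standard remedy, and the large-scale default remains
  "all";
* embedded-gold LOOCV, since the metric-only reading leaves nothing for the
  completion stages to recover and reduces to evaluating the raw projection.

With this preset the full pipeline reaches LOOCV AUC ≈ 0.6–0.7 across
generator seeds (permutation p < 0.01) while the projection-only arm sits
near 0.4 — the end-to-end evidence that each refinement stage contributes.
These numbers are recomputed, not stored, by `scripts/acceptance.py` and the
acceptance test suite.

## Numerical choices and edge cases

* Cosine of non-negative profiles is clipped to exact symmetry; zero-profile
  convention as above.
* KNN neighbour ties and CF neighbour ties break by entity index order
  (deterministic).
* CF denominators smaller than 1e-12 in absolute value trigger the ψ̂
  fallback.
* All matrix serialization uses `%.10g` TSV, making repeated runs from the
  same manifest byte-identical.
* Edge-list input: UTF-8 TSV, `#` comments, blank lines skipped, a third
  column ignored with a warning, malformed lines rejected with their line
  number.

## Known limitations

* The gradient-descent factorization is dense full-batch; cost is
  O(n_l·n_d·k) per iteration, fine to a few thousand × a few hundred but
  not beyond.
* No identifier normalisation: miRNA names must match exactly across the two
  input databases.
* The unbounded-CF degeneracy above also affects real data when the lncRNA
  set is small; users with narrow panels should bound the neighbourhood.
* Trapezoidal AUPR under heavy ties, as noted.
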