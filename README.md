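# organrep

Cross-lymphoid-organ antibody repertoire analysis in Python.

After immunization, B-cell clones expand, mutate and migrate between lymphoid
organs (bone marrow, spleen, axillary and inguinal lymph nodes).  `organrep`
quantifies that physiological landscape from per-organ IgG heavy-chain (VH)
sequencing tables: it groups reads into clones and clonotypes, measures
clonal expansion with Hill-number evenness profiles, measures clone sharing
and repertoire similarity between organs, builds CDRH3 sequence-similarity
networks, and tests for directional B-cell migration on lineage trees with a
maximum-parsimony switch-proportion (SP) permutation test.  A synthetic
multi-organ repertoire and lineage-tree generator makes every stage testable
without sequencing data.

It is a library for interactive/scripted use — the importable API plus the
short narrative scripts in `examples/` are the interface.

## Core definitions

- **Clone**: reads with identical germline V gene, J gene and CDRH3
  amino-acid sequence (optionally also CDRL3 in paired heavy+light mode).
- **Clonotype**: single-linkage cluster of clones with the same V/J, equal
  CDRH3 length and CDRH3 amino-acid identity > 90 % (threshold configurable) —
  a proxy for somatically related variants.
- **Hill diversity** of a clonal frequency distribution f:
  `D(α) = (Σ_i f_i^α)^(1/(1−α))`, with `D(0) = SR` (species richness) and
  `D(1) = exp(−Σ f_i ln f_i)`.  **Evenness** `E(α) = D(α)/SR` is 1 for a
  uniform repertoire and near 0 when a few expanded clones dominate;
  Shannon evenness `E(1)` is the headline expansion summary.
- **Jaccard index** `J(A,B) = |A∩B| / (|A|+|B|−|A∩B|)` on clone sets;
  **cosine similarity** `Σ A_i B_i / (‖A‖‖B‖)` on frequency vectors over the
  union of clones.
- **CDRH3 network**: nodes are clones of one clonotype, edges join pairs at
  amino-acid Hamming distance exactly 1.
- **SP statistic**: after maximum-parsimony (Sankoff, unit cost)
  reconstruction of internal organ states on each lineage tree,
  `SP[x→y]` is the fraction of all organ changes going x→y.  The SP test
  permutes tip organ labels (within each tree, or pooled among trees within a
  mouse), records `δ = observed SP − permuted SP` per replicate, and reports
  `p = #(δ ≤ 0)/replicates`; each replicate first down-samples trees to a
  maximum tip-to-change ratio (default 20) to control false positives.

## Worked example

Simulate lineage trees with a planted spleen → bone-marrow migration bias and
test for it (`examples/05_migration_sp_test.py`):

```python
from organrep import (SimulationConfig, biased_migration_matrix,
                      simulate_lineage_trees, sp_test)

organs = ("BM", "LN", "spleen")
cfg = SimulationConfig(
    organs=organs,
    migration_matrix=biased_migration_matrix(organs, "spleen", "BM", 0.15, stay=0.95),
    founder_organ="spleen", n_trees=30, tree_size_mean=18, seed=42,
)
trees = [t for t in simulate_lineage_trees(cfg) if len(t.organ_set) >= 2]
res = sp_test(trees, replicates=1000, seed=7)
print(res.p_values.round(3))
print(res.significant_pairs())
```

prints

```
           BM     LN  spleen
BM        NaN  0.953   0.976
LN      0.527    NaN   0.412
spleen  0.010  0.078     NaN
[('spleen', 'BM')]
```

i.e. 28.8 % of all parsimony-inferred organ changes ran spleen → BM
(`res.observed`), more than random label switching produces in 99 % of
replicates — the planted migration axis is recovered, and no spurious
direction is called.  `examples/01–04` walk through repertoire simulation,
evenness profiles, organ overlap/similarity and clonotype networks the same
way; each prints the numbers it computes and what they mean.

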