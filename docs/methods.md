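# Methods

This note documents the models and procedures implemented in `organrep`, the
assumptions behind them, the tunable parameters, and the design choices made
where the standard definitions leave room.

## Clones and clonotypes

Reads are aggregated into clones on the key (V gene, J gene, CDRH3 amino-acid
sequence), with germline calls truncated at the allele separator (`*`) because
clonal identity is defined at the gene, not allele, level.  In paired
heavy+light mode (single-cell data) the CDRL3 joins the key.  Per-organ clone
frequencies are read counts normalised within each (mouse, organ) sample, so
they sum to 1 per sample by construction.

Clonotypes — families of somatic variants — are connected components of the
link graph in which two clones are joined iff they share V and J, have equal
CDRH3 length, and exceed a CDRH3 amino-acid identity threshold (default
0.90).  Linkage is single-linkage, so chains of single mutants cluster even
when their endpoints are far apart.  The strictness of the boundary is
ambiguous in common usage ("> 90 % identity" vs "normalised Hamming distance
of 0.1", which differ exactly at identity 0.90); the default is strict
(identity must exceed the threshold) with an `inclusive` flag to admit the
boundary case.  Clonotype ids are assigned from a deterministic ordering of
clones and are stable across runs.

## Diversity and evenness

Hill diversity `D(α) = (Σ f_i^α)^(1/(1−α))` is evaluated on the positive
frequencies only; zero-frequency entries are dropped beforehand because
`0^0` makes the α = 0 endpoint ambiguous.  At α = 1 the closed form is
undefined and the Shannon limit `exp(−Σ f_i ln f_i)` is returned (this is the
value used for the headline Shannon evenness).  Evenness profiles default to
the grid α ∈ [0, 10] in steps of 0.2.  Input frequency vectors must sum to 1
within 1e-6 or a validation error is raised.  `D(α)` is non-increasing in α;
the test suite checks this and checks continuity across the α = 1 limit at
α = 1 ± 1e-5 (the derivative of D in α is of order D·Var(ln f), so continuity
tolerances must be read jointly with the evaluation point).

Expansion profiles report the summed frequency of frequency-ranked clone
bins; ties in frequency are broken lexicographically on CDRH3 so that ranked
output is reproducible.

## Somatic hypermutation load

SHM is the length-normalised Hamming distance between an aligned V-region
nucleotide sequence and its germline over IMGT positions 1–312 (configurable
end).  Positions carrying an ambiguous nucleotide (N) or gap in either
sequence are excluded from both numerator and denominator; a sequence with no
comparable positions yields a missing value rather than 0.

## Overlap and similarity

The Jaccard index works on clone-key sets; two empty repertoires give a
missing value, not 0.  Cosine similarity spans the union of clones of the two
repertoires (absent clones contribute 0) — the only convention in which
disjoint repertoires score exactly 0.  The printed textbook form sometimes
omits the square roots in the denominator; the implementation is standard
cosine similarity (with the square roots).

Organ-overlap analysis annotates each clone with its occupancy set and degree
and returns the exact Venn partition (all 2^k−1 cells); the partition is
refused above 16 organs to avoid combinatorial blow-up, while degree
histograms are always computed.

V-gene usage similarity counts unique clones per germline V gene per sample
— deliberately unweighted by clonal frequency, so one expanded clone cannot
dominate the usage signature — and correlates samples by Pearson r over the
union of V genes (absent genes count 0).  A constant usage vector has no
defined correlation and is reported missing.  The heatmap leaf order comes
from average-linkage hierarchical clustering on 1−r; the linkage choice is a
display convention and is exposed rather than hard-coded into any statistic.

Binder matching flags clones whose CDRH3 appears in an antigen-binding
CDRH3 list (the readout of display screening), optionally strict on V/J, and
reports binder/all ratios and clonal-frequency tables per overlap degree —
the inputs for specificity-vs-sharing correlation analyses.

## CDRH3 networks

Within a clonotype, clones are nodes and edges join pairs at amino-acid
Hamming distance exactly 1 (equal lengths only).  Node sizes are
log10(clonal frequency) linearly rescaled to [1, 10] per mouse; the range is
arbitrary and configurable.  Graph layout is left to viewers (GraphML
export); layout algorithms are cosmetic and nondeterministic, so they sit
outside the computational contract.

## Lineage trees and the SP migration test

Trees are rooted; the root is the basal ancestral node and the unmutated
germline sits implicitly above it, carries no organ state, and never
contributes transitions.  When reading Newick input, a tip labeled
`germline` is treated as the outgroup: the tree is rerooted on its branch and
the tip removed.

Ancestral organ states are reconstructed by Sankoff dynamic programming with
unit transition cost; the traceback resolves ambiguous most-parsimonious
states by preferring the parent's state (delaying transitions toward the
tips — a conservative choice for directional counting), then lexicographic
organ order.  An `average` strategy instead averages transition counts over
every most-parsimonious labeling (exhaustive enumeration; small trees only).
Both strategies realise exactly the minimum change count.

Clusters of internal nodes joined by zero-length branches (polytomies
serialised as arbitrary bifurcations) are reordered by greedy
nearest-neighbour-interchange moves restricted to zero-length edges,
accepted only when they reduce the parsimony change count.  Moves include
exchanges between two zero-length sibling clades, which is necessary when
the root subdivides a polytomy.  The result never has more changes than the
input and reapplication is a fixed point.

The SP statistic normalises directional change counts by the total number of
changes over all trees.  The permutation test, per replicate: (i) each tree
is down-sampled uniformly at random until tips ≤ cap × changes (default cap
20; pruned topology collapses unary nodes and sums branch lengths, and is
never re-estimated), re-drawn every replicate; (ii) tip labels are permuted
within each tree (`within_tree`, directional pairs) or pooled and reshuffled
among trees within each mouse (`among_trees`, unordered pairs summed over
both directions — the pooled shuffle preserves the per-mouse label
multiset); (iii) δ = observed − permuted SP is recorded per pair, with the
observed side recomputed on the same down-sampled trees so the comparison is
paired.  `p = #(δ ≤ 0)/replicates` per pair.  Degenerate inputs (no
transitions anywhere) give missing p-values with a warning.

Pre-tree filters follow the standard pipeline rules exactly: sequences with
fewer than 3 supporting reads are discarded (when counts are available),
clones are down-sampled to at most 100 sequences, and clones with fewer than
10 sequences or from a single organ are removed.

## Synthetic data generator

The generator emulates the structure of a two-cohort immunization study: six
lymphoid organs × three mice per cohort, heavy-tailed clone frequencies,
partial organ sharing, somatic CDRH3 variants, and lineage trees with
Markov tip-organ evolution.  Defaults (300 founder clones/mouse, 3000
reads/organ, power-law exponent 1.3, Poisson(2) variants per founder,
CDRH3 length ~ N(14, 2) clipped to [8, 22]) were chosen once as desk-scale
stand-ins for deep-sequencing repertoires.

- Clone frequencies follow rank^(−s) modulated by lognormal noise; the
  exponent may be global or per organ.  The cohort presets encode the
  qualitative study conditions: cohort-1x uses exponents 1.9 (lymph nodes),
  1.5 (spleen), 1.2 (bone marrow) and sharing probability 0.05; cohort-3x
  uses a uniform exponent 1.6 and sharing 0.35.
- Somatic variants copy a random existing family member with ≥ 1 CDRH3
  substitution (count drawn as Binomial(L, shm_rate), floored at 1 and
  capped so the family stays one single-linkage clonotype at the 90 %
  threshold); no indels, so clone keys keep fixed length.
- Counts are multinomial draws per organ; `count_mode="expected"` rounds
  expected counts instead, for exactly reproducible frequency vectors.
- Tree topologies grow by uniform tip splitting (Yule); tip organs evolve
  from a founder organ by one application of the migration matrix per branch
  (the SP test counts discrete transitions, not rates; a per-length Poisson
  mode exists).  True simulated transitions are stored per tree for oracle
  comparison.  A migration matrix with identical rows makes tip labels
  i.i.d. — the exchangeable null used for calibration.

What the generator does *not* emulate: germinal-centre dynamics and
selection, isotype switching, sequencing error (inputs model error-corrected
consensus reads), V(D)J recombination statistics, and the read depths of real
experiments.  Passing tests therefore demonstrate correctness and
calibration of the *methods* under the stated statistical structure, not
biological fidelity of any particular number; absolute values of e.g.
evenness or shared-clone counts scale with sampling depth.

## Problem sizes used in the checks

The calibration study uses 200 null datasets of 6 trees (~16 tips, 3 organs)
with 500 permutation replicates; the empirical type-I error at nominal 0.05
is compared against its exact binomial confidence interval and the p-value
distribution against uniformity (KS, 1 % level).  Power is estimated over 50
simulations of 30 trees (~18 tips) with a planted spleen→BM migration
probability of 0.15 (stay 0.95), 200 replicates each; this effect size was
fixed at the first calibration run.  Oracle comparisons use exhaustive
enumeration (trees ≤ 8 tips), brute-force all-pairs linkage (≤ 50 clones)
and brute-force Hamming adjacency (≤ 200 clones).

## Known limitations

- Tree topologies are consumed or simulated, never inferred; branch lengths
  are informational except for the zero-length polytomy rule.
- The greedy NNI polytomy reordering finds a local optimum of the change
  count, not necessarily the global one.
- The `average` parsimony strategy enumerates labelings and is exponential
  in the worst case; it refuses beyond 100 000 labelings.
- Venn partitions are exact and therefore capped at 16 organs.
- Binder matching by CDRH3 alone can conflate convergent sequences from
  different V/J backgrounds; the strict mode exists for that reason.
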