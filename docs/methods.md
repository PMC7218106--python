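# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic benchmarks
do and do not demonstrate.

## Network integration

The integrated network is the union of a gene–gene interactome and a
bipartite SNP–gene layer. The SNP layer is built in three steps:
proxy SNPs are replaced by the GWAS index SNP they tag (the LD proxy
table is consumed precomputed; linkage computation from genotype panels
is out of scope), nominal eQTL p-values are adjusted by
Benjamini–Hochberg (via `statsmodels.stats.multitest`) and thresholded
at FDR ≤ 0.05, and the surviving SNP–egene pairs whose gene exists in
the interactome are added as edges (pairs pointing outside the
interactome are dropped and counted). Choices the sources leave open:

- **Duplicate-edge collapse.** Replicated interactome lines keep the
  maximum weight (they are redundant evidence); repeated SNP–gene
  evidence sums; several proxies of one index SNP hitting the same gene
  collapse to the minimum nominal p (strongest evidence).
- **eQTL edge weight.** Default 1.0, identical to interactome edges; a
  −log10(p) scaling is available (`eqtl_edge_weight`). Nothing
  downstream assumes a particular scale.
- **Expression filter.** A gene is kept when its expression statistic
  is ≥ 0.1 (configurable); genes missing from the table count as 0.
  The statistic itself (median TPM, mean count, …) is the caller's
  choice — the filter only compares numbers.

## Embedding

Walks are second-order biased random walks: from v (previous node t)
the walk moves to x with probability α_pq(t,x)·w_vx / Z, with
α = 1/p, 1, 1/q for t–x distances 0, 1, 2. The first step of each walk
is weight-proportional (no previous node). Defaults: p = q = 1 (the
first-order special case, which admits O(log deg) sampling through
per-node cumulative weights), walk length 80, 10 walks per node,
window 10, d = 128, 5 epochs. On directed graphs walks follow edge
direction and the d_tx test uses the symmetrized adjacency, so the
return/in-out biases keep their meaning.

The skip-gram objective is optimized by negative sampling (k = 5 draws
from the unigram^0.75 noise distribution per positive pair) — the exact
softmax partition over all nodes is intractable and negative sampling
is the standard surrogate. Training is a single-threaded numba kernel
with a linearly decaying learning rate (0.025 → 0.025·10⁻⁴), reduced
windows (b ~ U{1..window}), and an explicit xorshift64* PRNG; a given
seed therefore reproduces walks and embeddings bit-for-bit. Nodes never
visited by a walk (isolated nodes) keep their random initialization and
are reported in the log.

## Hierarchical clustering and the tree cut

Embeddings are clustered with average linkage on Euclidean distances
(`scipy.cluster.hierarchy`). The cut emits a branch as a module when

1. N > N₀ (minimum module size),
2. the branch forms below the height cap h_max (default: the 99th
   percentile of merge heights; absolute override supported),
3. its core scatter d̄ < d_max, where the core is the
   N_c = min(⌊N₀/2 + √(N − N₀/2)⌋, N) lowest-merging leaves and d̄
   their mean pairwise dissimilarity,
4. its gap g = (attach height) − d̄ > g_min, the attach height being
   the height at which the branch merges into the rest of the tree
   (for the tree root, its own height).

The gap deliberately measures *separation*: a tight branch far below
its attachment point has small d̄ and large g, whereas a branch whose
core already spans its full height is not a meaningful cluster. The
N_c expression is the published Dynamic Hybrid core-size rule and is
pluggable.

The cut itself is bottom-up: merges at or above h_max are suppressed;
walking the remaining merges in order, when two branches that *both*
qualify meet, they are locked as separate modules and their union
becomes a composite that is never itself emitted; a branch meeting an
already-composite partner is locked iff it qualifies; branches alive
after the last merge are locked iff they qualify. This makes nested
structure resolve to the most specific qualifying branches without any
extra tie rule, and reduces to the intuitive answers in the degenerate
cases (one tight cloud → one module; parameters unsatisfiable → no
modules). Leftover leaves ("outliers", label 0) are then attached to
the cluster with the smallest average dissimilarity to its stage-1
members — average linkage, consistent with tree construction; ties go
to the lower module id; stage-1 labels never change.

`deepSplit` ∈ {0..4} sets (d_max, g_min) by interpolating the
core-scatter cap from 0.64 (conservative) to 0.95 (aggressive) of the
height range above its 5th-percentile base, with
g_min = 0.75·(1 − frac)·range — so aggressive settings accept looser
cores and smaller gaps, yielding more, finer modules.

## Iterative module selection

Modules without a single egene are discarded; surviving genes plus the
SNP nodes still adjacent to one of them form the next round's node set;
clustering repeats until nothing is filtered (the partition is then a
fixed point) or `max_iter` (default 20) is reached. By default the
full-network embedding is re-used, restricted to surviving nodes —
re-running the cut on identical vectors makes the stability test exact
and the loop deterministic. `reembed_each_iter=True` recomputes walks
on each induced subnetwork instead; it is slower, stochastic across
iterations, and covered by the same tests. Termination is guaranteed:
each iteration either strictly shrinks the node set or stops.

## Enrichment

Egene over-representation per module uses the one-sided Fisher exact
tail P(X ≥ a) of the 2×2 table (a = in-module egenes) over the
gene-only background; SNP nodes never enter any table. The
hypergeometric point probability is also exposed (`point_probability=
True`) since a point mass is occasionally wanted for reporting, but it
is not a test and not the default. Probabilities are evaluated in log
space via `scipy.stats.hypergeom`; tests verify them against an
independent log-factorial enumeration oracle to |Δlog p| < 1e-9.
Gene-set over-representation against GMT collections uses the same
arithmetic with the gene set in place of the egene margin, BH FDR
across the collection, and reports the top 50 terms by p.

Module eigen-features are the first right singular vector of the
column-centered member-embedding matrix (unit norm, first non-zero
loading positive; singletons contribute their own normalized vector).
The module dendrogram applies average linkage to 1 − Pearson ρ between
eigen-features; a zero-variance eigen-feature is an error naming the
module.

## Evaluation

Predicted and ground-truth partitions are compared on their shared
node universe. The overlap-count matrix is zero-padded to square and
the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`,
maximizing) finds the bijection with maximal total overlap; a
vanishing perturbation keeps tie-breaking deterministic without ever
changing the integer objective. Matched pairs contribute
TP = |P_i ∩ T_j|, FP = |P_i| − TP, FN = |T_j| − TP (padding
contributes zeros), pooled into micro precision, recall and F1.

## Synthetic benchmarks

**LFR-style networks.** Degrees follow a truncated power law with
exponent t1 whose lower cutoff is solved so the mean matches k, capped
at maxk; community sizes follow a power law with exponent t2 between
the minimum degree and maxk. Each node's internal degree is
(1 − μ_t)·degree; internal edges come from per-community configuration
models and external edges from a global stub matching that forbids
within-community pairs (unmatched stubs are dropped, so realized
degrees sit slightly below target — tests require the mean within 15%
of k). Edge weights are assigned so each node's external *weighted*
degree share targets μ_w in expectation (exact per-node enforcement is
the reference tool's iterative step and deliberately not replicated);
μ_w = 0 drives the between-community weight share below 1e-9.
Topological mixing μ_t defaults to μ_w — one mixing knob, as in the
benchmark convention. Components are bridged to the giant component
post hoc. A `directed` flag randomizes edge orientation for
directed-walk testing. The generator approximates, not replicates, the
reference LFR tool; the benchmark comparison tolerance (±0.15 micro
F1) reflects that.

The benchmark reproduction runs the four parameterizations
(100,10,30), (500,10,50), (1000,20,100), (2000,30,200) at μ_w = 0.5
with cut settings (6,2), (4,3), (6,3), (5,2) and default embedding
parameters, reporting the median mapped micro F1 per configuration.
Seed-to-seed spread grows as networks shrink (sd ≈ 0.15 at N = 100),
so the reproduction script uses 15/11/7/5 replicates for the four
sizes respectively — enough to stabilize the median while keeping the
full sweep around ten minutes on one CPU.

**Planted-disease triplets.** A stochastic-block interactome (default
eight 25-gene modules, p_within = 0.3, p_between = 0.01) with egenes
planted in the first three modules (10 per module, signal eQTL
p-values ≤ 1e-8 through proxy SNPs tagging one index SNP per module)
plus uniform-noise eQTL records and an expression table with a
configurable low-expression fraction. The egene density (40% within
disease modules) mirrors the strong enrichment seen in real
case-study modules; under BH at 0.05 the uniform noise contributes
essentially nothing. These data exercise every integration branch
end-to-end but are far smaller and cleaner than a real interactome:
passing them shows the machinery is correct, not that the method's
biological discoveries replicate.

## Numerical and degenerate-input conventions

Transition distributions normalize exactly (Σ = 1 within 1e-12,
asserted in tests); sink nodes truncate walks; empty partitions and
collections return empty results rather than raising; an all-zero
partition survives outlier assignment unchanged with a warning; BH
rejects p-values outside [0, 1]; dendrograms reject non-finite
vectors. Scipy's merge order resolves dendrogram ties
deterministically, and all stochastic components take explicit seeds.

## Known limitations

- Multi-worker (parallel) embedding training is not offered; seeded
  determinism requires the single-threaded kernel.
- The tree cut implements the four qualification conditions plus
  bottom-up locking only — the reference Dynamic Hybrid's PAM-like
  re-assignment against eigen-features and further branch heuristics
  are out of scope.
- Overlapping communities, directed LFR degree sequences (beyond
  orientation randomization), and GSEA-with-ranking are unsupported.
- Real GWAS/eQTL case studies require external data (GTEx-scale eQTL
  summaries, an interactome); the pipeline logs the equivalent counts
  (significant associations, egenes, eSNPs, dropped records, network
  sizes) when given such inputs, but no such dataset ships here.
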