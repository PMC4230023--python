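# Methods

## Model and assumptions

A PPI network is an undirected graph over opaque protein identifiers with
positive edge weights (1.0 throughout for unweighted data).  A complex is a
set of proteins; complexes may overlap, and the pipeline is deliberately
*not* restricted to dense subgraphs — a candidate complex is any spoke
neighborhood of a sufficiently important, topologically clean protein,
refined afterwards by a separation criterion (cohesiveness).  Isolated
proteins and self-interactions carry no information for this model:
self-loops are dropped at parse time and degree-≤1 proteins can never seed
a complex of the minimum size 3.

## Stage details and numerical choices

**Reliability scoring (AdjustCD).**  Scores use self-inclusive
neighborhoods `N_u = {u} ∪ neighbors(u)`.  Round one:
`score(u,v) = 2|N_u ∩ N_v| / ((|N_u|+λ_u) + (|N_v|+λ_v))` with
`λ_u = max(0, n̄ − |N_u|)`, where `n̄` is the mean neighborhood size; the λ
term keeps low-degree pairs from looking spuriously reliable.  In round
k > 1 the counts become sums of round-(k−1) scores over the same
neighborhoods, with the self-score `w(u,u)` pinned at 1; λ is kept at its
count-based value across rounds.  This keeps scores symmetric and in
[0, 1] (the numerator is bounded by the two own-neighborhood sums).  The
default is two rounds; one round reproduces the plain smoothed
Czekanowski–Dice similarity.  Scores decide pruning only — surviving edges
keep their input weights, since reliability and interaction confidence are
different quantities.  Default thresholds: 0.2 (weighted), 0.45
(unweighted).  Duplicate edge lines in input files keep the maximum weight
(a conservative reliability choice; any fixed rule would do, this one is
documented and tested).

**Noise filtering.**  The three noise categories are qualitative by
definition; the package fixes testable cutoffs: fjord = neighbor-induced
subgraph density < 0.1, shore = some neighbor of degree ≤ 1, both
configurable.  Precedence when several apply is bridge > fjord > shore
(any fixed order suffices; this one is asserted by tests).  Degree-≤1
proteins are labelled shore outright.

**Ranking.**  Power iteration for `r = (1−d)/n + d·Mᵀr`, `d = 0.85`,
L1 stopping tolerance 1e-9, cap 200 iterations (warning on
non-convergence, last iterate returned).  Transition probabilities are
weight-proportional, so unweighted networks walk uniformly; isolated nodes
teleport uniformly.  Scores are renormalized to sum to 1 and all ties in
downstream orderings break lexicographically, making runs bit-reproducible.
Note one consequence of these semantics on toy graphs: leaves forward their
whole damped mass to their only neighbor, so a path internal next to two
leaves can outrank members of a small clique elsewhere in the graph; seed
order simply follows the computed scores.

**Detection.**  One spoke complex (seed + all neighbors) per essential
protein, visited in decreasing rank; minimum size 3; exact-duplicate
member-sets keep the earliest (highest-ranked) seed.  Noise proteins may
appear as non-seed members — the spoke model takes all neighbors.

**Merging.**  Essential-protein overlap uses the containment denominator
`|E1 ∩ E2| / min(|E1|, |E2|)` so that a small complex nested in a larger
one always merges; a Jaccard alternative is available
(`MergeParams.overlap_mode`).  The threshold comparison is strict (>
0.75), the cohesiveness acceptance is non-strict (≥), and the penalty
defaults to `p = 2.0` — interpretable as two units of unobserved
interaction weight per candidate complex.  Expansion scans the proteins
initially in the merged complex lexicographically, each one's neighbors
lexicographically, admitting candidates immediately (the working set grows
during the scan); expansion only ever adds proteins.  Passes repeat to a
fixpoint (each merge strictly reduces the complex count, so termination is
guaranteed) with a cap of 100 passes as a safety valve.

**Evaluation.**  PPV is defined as 0 when the prediction shares no protein
with the reference (the formula is otherwise 0/0).  MMR uses an exact
maximum-weight bipartite matching (Hungarian algorithm), not a greedy one;
all ω > 0 edges participate by default, with an optional edge threshold.
Match counting uses strict ω > 0.25.  Reference complexes are taken as
given, including members absent from the network.

## Synthetic benchmark generator

`PlantedModel` plants `n_complexes` Erdős–Rényi subgraphs (re-sampled until
connected) at within-complex density `p_in`, connects every remaining node
pair with probability `p_out`, and optionally makes consecutive complexes
share one hub member (`overlap_fraction`) — the overlap topology that
motivates allowing a protein in several complexes.  Defaults: 10 complexes
of sizes 4–8, `p_in = 0.9`, `p_out = 0.01`, weights uniform in
[0.5, 1.0] (confidence-like scores; `weight_noise=None` gives an unweighted
network).  Everything is a deterministic function of the seed.

What the generator does *not* emulate: heavy-tailed degree distributions,
bait–prey spoke-sampling artefacts, correlated false negatives, or
biological identifier structure.  A green recovery test therefore
establishes that the pipeline's stages compose correctly and recover
planted modular structure at mild noise — not that it would reach any
particular score on a real interactome, which depends on dataset and
catalog versions.

`random_partition` provides the chance-level baseline used in recovery
experiments: the same proteins shuffled into complexes of the ground-truth
sizes.

## Degenerate inputs and edge cases

Empty networks cannot be scored or ranked (error); an all-noise network
yields an empty prediction (warning, not an error).  Writing an empty
complex set produces an empty file plus a warning, and loading an empty
catalog is an error.  Cohesiveness of an edgeless set at `p = 0` is defined
as 0.

## Known limitations

* The merge procedure's complexity is quadratic in the number of detected
  complexes per pass; very dense seed neighborhoods on large interactomes
  make merging the dominant cost.
* Expansion cannot remove proteins, so an over-large union is never pruned
  back; only exact duplicates are removed afterwards.
* The pairwise-similarity ranking criterion used by an earlier variant of
  this approach is intentionally absent (it is expensive and contributes
  little); rankings are purely topological.
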