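# Methods

`supertreesim` studies how well supertree methods reconstruct a known
species tree from estimated source trees, as a function of how the source
trees sample the taxon set. This note describes the models, the
algorithms, their tunable parameters, and the design decisions taken where
the literature leaves the construction open.

## The simulation model

**Model trees.** Species trees are generated under a pure-birth (Yule)
process (`dendropy`'s birth–death simulator with death rate 0). The
simulation stops at the *n*-th birth, which leaves the newest two tips with
zero-length branches; all tips are therefore extended by one
Exponential(*n·λ*) waiting time, keeping the tree ultrametric. The tree is
rescaled to a root-to-tip height of `tree_height` (default 1.0 expected
substitutions per site — enough signal for gene-length alignments while
leaving short deep edges genuinely hard), and each branch is then
multiplied by an independent lognormal factor with log-sd `deviation_sd`
(default 0.5; 0 recovers a strict molecular clock). Leaves are labelled
`T01..Tn`.

**Genes and missing data.** Each gene occupies a rooted subtree of the
(dataset-restricted) model tree: it is gained on one edge, sampled with
probability proportional to branch length (a virtual stem edge of weight
`stem_weight`, default half the total tree length, lets genes span all
taxa), and lost independently on each edge below the gain with probability
`1 − exp(−loss_rate · length)` (default `loss_rate` 0.4/substitution);
a lost edge prunes its whole subtree, so gene leaf sets are always unions
and differences of clades, never arbitrary subsets. Genes with fewer than
`min_gene_leaves` (default 4) survivors are resampled. Under the defaults
the median gene covers ≈ 60% of its dataset's taxa.

**Sequences.** Gapless DNA alignments evolve down the gene subtree under
GTR+Γ+I: root states from the stationary frequencies; per-site rate 0 with
probability `p_inv`, else Gamma(α) with mean 1; transition probabilities
from the eigendecomposition of the normalized GTR rate matrix (one
expected substitution per unit branch length at rate 1). Two named
parameter presets ship (`default`, an empirical-style unequal-rates
matrix with α = 1 and p_inv = 0.2, and `jc`, equal rates); they are
configurable stand-ins, not reproductions of any published estimate.

**Datasets.** A *mixed* profile holds one scaffold dataset — a uniform
random sample of `round(p·n)` taxa, where `p` is the scaffold density,
carrying 4 genes — and `n_clade_datasets` (default `max(4, n // 5)`)
clade-based datasets, each the full leaf set of a random rooted subtree
with between `clade_size_min` (5) and `⌈n/2⌉` leaves, carrying 3 genes.
An *all-scaffold* profile replaces every dataset by an independent random
sample of the same density. Scaffold genes are gained at the root of the
scaffold's restricted subtree ("universal markers"), because a sparse
random sample whose genes each occupy small clades would frequently leave
taxon pairs with no shared data; clade genes follow the full gain/loss
process. A dataset keeps only taxa covered by at least one of its genes.

**Source-tree estimation.** The built-in estimator is neighbor joining
(scikit-bio) on Jukes–Cantor-corrected distances of the concatenated gene
alignments with pairwise deletion. Saturated pairs (≥ 3/4 mismatches)
fall back to the uncorrected fraction; pairs sharing no sites are imputed
by a min-plus closure through intermediate taxa, which keeps the matrix
tree-like instead of injecting arbitrary constants. A configuration hook
(`estimator={"command": ...}`) shells out to any external
maximum-likelihood program that reads FASTA and prints newick, and
`estimator="true"` substitutes the exact restriction of the model tree
(the oracle mode used by the clean-recovery tests). Under the defaults the
estimated source trees carry moderate error (clade trees mostly exact,
scaffold trees FN ≈ 0.1–0.3 depending on density) — deliberately
"reasonably but not extremely accurate" inputs.

## Quartet encodings

A source tree `t` can be handed to the amalgamation heuristic as:

- **All** — every induced resolved four-taxon tree (C(n,4) for binary `t`);
- **Geo+TSQ** — each quartet kept with probability `d⁻³`,
  `d = diam_t(q)` its topological diameter (the largest leaf-to-leaf
  edge-count distance among its four leaves), plus all TSQs;
- **Exp+TSQ** — the same with probability `1.5⁻ᵈ`.

The Topologically Short Quartets (TSQs) of an internal edge take, from
each of the four subtrees hanging off the edge's endpoints, the
topologically nearest leaf (all tied leaves), pairing same-side subtrees;
around a polytomy every pair of same-side subtrees contributes. Inclusion
draws are independent Bernoulli per 4-subset, seeded; the probabilities
are taken literally (no normalization or cap — `d ≥ 2` keeps them < 1).
Per-tree encodings are combined into a weighted multiset (weight = number
of contributing source trees; conflicting topologies on the same four
labels coexist), with a plain-set `deduplicate` flag.

## Supertree methods

**MRP / gMRP.** Each internal edge of each source tree becomes a partial
binary character (side containing the tree's lexicographically smallest
leaf → 0, other side → 1, absent taxa → `?`; polarity is irrelevant for
parsimony length but fixed for byte-stable matrices). The parsimony
search is a ratchet: per start, a greedy random-addition tree is improved
by alternating nearest-neighbor-interchange climbs and
subtree-prune-regraft sweeps under vectorized Fitch scoring (`?` = free
state set {0,1}); each ratchet iteration doubles the weight of a random
quarter of the columns, climbs, restores the weights and climbs again.
All distinct topologies at the best score (capped at 50) are collected and
their greedy consensus — bipartitions accepted by decreasing frequency,
ties broken by canonical lexicographic form then input order, each
accepted only if compatible with its predecessors — is the gMRP tree.
API defaults are 25 iterations, 25% reweighting, 5 starts; the scaled-down
benchmark and acceptance script use 3 iterations and 2 starts, which on
32-taxon profiles lands within ~1 step of the true tree's score.

**Quartet amalgamation ("QMC-style").** The published description of
quartet max-cut heuristics is a contract (polynomial time, no MQC
guarantee); the machinery here is this package's own design:

1. *Recursive partition.* At each level a cut of the current taxa is
   sought by seeded hill climbing (single-taxon flips, 8 restarts, both
   sides kept non-empty), scored per quartet: a 2-2 split with both pairs
   intact earns the quartet's weight (its topology is realized), a split
   that breaks a pair loses `lambda_good` (default 2.0) times the weight
   (the quartet becomes undisplayable), and 3-1/0-4 splits are neutral
   (deferred). This score is exactly aligned with Maximum Quartet
   Consistency: on compatible inputs a true edge cut incurs zero penalty.
   A pairwise good/bad edge-graph max cut provides a warm start. An
   important negative result drove this design: the plain edge-graph
   objective (cut bad minus λ·cut good) has non-edge global optima on
   sparse encodings — enumeration on 10-leaf TSQ instances shows a
   "garbage" cut beating every edge cut at any λ — so it cannot serve as
   the primary objective.
2. *Signal propagation.* Recursing into a side, quartets fully inside are
   kept; quartets with three members inside keep their signal with the
   outside taxon replaced by a single representative of the rest of the
   tree; an intact pair straddling the cut persists as a two-taxon
   cohesion constraint; incoherent straddlers are dropped and counted.
   Dropping everything that straddles would leave 3-taxon sides with no
   signal and provably cannot recover even a compatible 6-leaf input.
3. *MQC polish.* The assembled tree is refined by iterated local search
   directly on total satisfied quartet weight: steepest NNI climbs
   alternating with subtree-prune-regraft sweeps, random multi-NNI kicks
   to escape plateaus (stopping early once every quartet is satisfied),
   and a second start from neighbor joining on the quartet-separation
   fraction (share of quartets placing a pair on opposite sides). Leaf
   distances for quartet evaluation are computed as sums of
   edge-indicator outer products, which keeps each tree evaluation a few
   hundred microseconds at n = 32.

With All-quartet input the method recovers random 6–10-leaf trees from
their own encodings essentially always, and 16-taxon compatible profiles
exactly under all three encodings.

## Evaluation

FN rate = |Σ(T₀) \ Σ(T)| / |Σ(T₀)|, FP rate = |Σ(T) \ Σ(T₀)| / |Σ(T)|
(defined 0 for a star estimate, the convention that keeps conservative,
highly unresolved supertrees finite), RF rate = their mean; all trees are
compared as unrooted bipartition sets. Distance to the profile restricts
the supertree to each source tree's taxa and aggregates as a ratio of
sums (Σ differences / Σ edges; a mean-of-ratios mode is a flag). The
model tree is restricted to the supertree's leaf set before scoring, since
taxa sampled by no dataset cannot be placed by any method. Replicates on
which any requested method fails are excluded from every method's means
(complete-case comparison). The correlation study ranks methods within
each replicate by each Sum-criterion and each true-error metric and
summarizes the per-replicate Spearman correlations (mid-rank ties;
zero-variance cases are undefined, flagged, and excluded) as mean and
range per condition — a 4-density × 3-criterion × 3-error table.

## Benchmark problem sizes

The packaged benchmark (tests and `scripts/acceptance.py`) runs 32-taxon
profiles, scaffold densities {20, 50, 75, 100}% mixed plus 20%
all-scaffold, 10 replicates per condition, 500 sites/gene, built-in
estimator — chosen as the smallest design in which the taxon-sampling
effects are unambiguous: mean FN falls steeply and monotonically with
scaffold density, and sparse all-scaffold profiles are far harder than
mixed profiles at equal density. Absolute error levels at 32 taxa are
higher than at production scale (a 20%-density scaffold holds only 6
taxa), so trends and orderings, not absolute rates, are the meaningful
output. The architecture streams quartet subsets and never materializes
per-tree encodings beyond C(n,4) arrays, so larger runs are a matter of
wall-clock, not memory.

## What the simulator does not model

No insertions or deletions (the true alignment is known by construction),
no alignment estimation error, no rate variation across genes beyond the
per-site Gamma+I mixture, no horizontal transfer (gene histories are the
species tree restricted to the gene's leaf set), and the built-in
distance estimator is not maximum likelihood — passing tests demonstrate
correct behavior of the supertree machinery under these idealized inputs,
not field performance on real alignments.

## Degenerate inputs and numerical choices

Zero-length branches are legal and never collapsed implicitly. Midpoint
rooting breaks ties between equal longest paths toward the
lexicographically smallest leaf pair and requires explicit branch lengths
(pass unit lengths to root by edge counts). Restriction to fewer than 3
taxa, duplicate labels, and negative lengths are errors. An empty quartet
set or an all-`?` character matrix yields a star tree. Fitch scoring and
topology hashing use exact integer arithmetic; cut search uses a 1e-12
improvement threshold; distance-matrix symmetry is enforced exactly
before neighbor joining (floating summation order would otherwise break
the scikit-bio validator).
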