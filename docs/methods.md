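# Methods

## Network model and evidence algebra

An interaction is the pair (TF, target gene) with merged annotation; the
pair is the identity, so multiple records (publications) for the same pair
collapse into one interaction. Evidence is stored as two orthogonal booleans
(`has_binding`, `has_expression`) rather than as mutually exclusive labels:
the evidence sets B, E, B&E, B|E are then simple filters and the
inclusion–exclusion identity |B|+|E|−|B&E| = |B|E| holds structurally. The
mutually exclusive reading (binding vs expression-only) is recoverable as
B vs E∖B; the orthogonal storage is the only one under which the published
yeast counts (45,209 + 161,747 − 11,486 = 195,470) are consistent.

Signs come only from expression evidence. Aggregation across publications:
all-positive → positive, all-negative → negative, any explicit dual or a
positive/negative conflict → dual. Undirected ("unknown") observations never
override a consistent directional sign — the published rule covers only the
three directional outcomes, and discarding direction because one study could
not call it would destroy information; only-unknown stays unknown.
Associations with no evidence annotation at all are dropped at read time
with a logged count.

Gene identifiers are uppercased and matched exactly; no alias resolution
against genome databases is attempted, so cross-network overlaps are lower
bounds under inconsistent naming.

Density is 100·|E|/(n_TF·n_nodes): the denominator allows TFs to target TFs
and themselves, which is what the worked yeast example (152 × 3937 =
598,424) dictates; it is **not** n_TF·n_TG. Percentages are rounded
half-even to 2 decimals for table parity; raw values are kept internally.

One published overlap share is not reproducible from its own printed counts
(10,909/45,209 = 24.13%, printed as 24.26%); the package reports the
recomputed value.

## Degree analysis

Degrees count distinct interaction partners (never publications or
conditions); self-loops add one to both degrees of their node, since
auto-regulation is a genuine regulatory edge. In-degree distributions follow
the literature convention of excluding unregulated nodes (in-degree 0),
reporting the excluded count; the variant without exclusion differs only in
the degree-0 entry. Out-degree distributions are binned into half-open
ranges of configurable width (default 200, matching the published figures),
with optional truncation. TF rankings (top/bottom k by out-degree) include
all ties with the k-th value and report that value as the threshold — the
returned set can exceed k; the exact historical tie policy is unstated, and
tie inclusion is the only order-independent choice.

## Functional binning

Genes carry one major functional category (supplied as a TSV; the package
does not train the text classifier that originally produced such
annotations — the annotation table is an input). Consecutive in-degrees are
merged into bins by a greedy left-to-right agglomeration: the accumulated
bin is compared with the next in-degree's category counts by a chi-squared
test on the 2×C table (`scipy.stats.chi2_contingency`, no continuity
correction); the degree joins the bin while p > α (default 0.05), otherwise
a new bin starts. Columns with expected count below `min_expected` (default
5) are pooled into an "other" column before testing; a degree slice with
zero total merges unconditionally with a warning. The published procedure
names neither the scan order, α, nor the small-count handling, so all three
are exposed as configuration; the published bins (1–4, 5–9, 10–25) are one
possible outcome, not a promised one. The output always satisfies the bin
contract: contiguous, disjoint intervals starting at in-degree 1 and
covering the observed range, invariant under category relabeling.

## Triad census and significance profiles

Self-loops are stripped before any triad work: auto-regulation is a 1-node
motif and the 13-class taxonomy of connected 3-node digraphs is closed only
without it. Classification canonicalizes the 6 off-diagonal adjacency bits
over all 6 node permutations; the display ordering 1..13 follows the triad
significance profile convention (two-edge triads first, feed-forward loop at
7, mutual pair with common target at 10, complete triad at 13) and lives in
one editable table (`TRIAD_REPRESENTATIVES`) that every downstream output
keys on. The production census delegates to the standard fast triadic
census in networkx and folds the 16 census names onto the 13 connected
classes via the package's own canonicalizer; a brute-force all-triples
oracle ships alongside and the two are required to agree by property test —
the dual route is the correctness argument.

The null model is degree-preserving edge switching: ⌈swap_factor·|E|⌉
attempted swaps (a→b, c→d) → (a→d, c→b), rejecting self-loops and duplicate
edges, with an option to also preserve the mutual-dyad count (off by
default — the historical analyses specify only "random networks of the same
dimensions"). Default swap_factor 10 per edge; replicate seeds spawn from a
base seed, so ensembles are exactly reproducible. Z-scores use the ensemble
mean and population standard deviation; z is forced to 0 for classes with
fewer than 4 real occurrences (the standard rare-motif correction) and for
degenerate (zero-std) classes, the conservative choice for a case the
original tooling leaves undefined. Zeroing precedes the unit-length
normalization SP_i = z_i/(Σ z_j²)^½; an all-zero vector maps to itself.

Ensemble size defaults to 1000 for desk runs (the historical analyses used
10,000); the enrichment properties asserted in the test-suite hold from
R ≈ 200, which is what the benchmark tests use to stay fast.

## Synthetic generator

The generator emulates: a bipartite-leaning TF→TG structure; heavy-tailed
out-degrees (zipf/discrete power law, default α = 2.0, or fixed); light-
tailed in-degrees (geometric, default p = 0.35 giving mean 1/p ≈ 2.86
regulators per gene, in the range of the curated doubly-supported yeast
network, or shifted Poisson); evidence fractions defaulting to the curated
Venn partition (0.7687, 0.1725, 0.0588); sign fractions (0.55, 0.30, 0.05,
0.10 for positive/negative/dual/unknown — activation dominates curated
yeast data, dual effects are rare); condition tags as independent Bernoulli
marks; reference sets of size 1 + Poisson(0.61), matching the published
mean of 1.61 references per interaction.

Wiring realizes each TG's drawn in-degree exactly (capped at the TF count)
by sampling that many distinct TFs with probability proportional to the
TF's drawn out-degree weight. The in-degree law is therefore reproduced
faithfully — which the parameter-recovery checks require — while realized
out-degrees inherit the heavy tail of the weights rather than equaling the
drawn values; the ledger records the drawn values and every oracle works
from realized quantities. Planted motif instances are vertex-disjoint on
fresh nodes, so planted counts are exact lower bounds in the census.

The ledger records every assignment (evidence class, sign, tags, reference
sets, planted locations) and fully determines the network; ledger replay of
the Venn partition, condition-filter counts and reference-support means is
asserted to match the analysis modules exactly.

What the generator does **not** emulate: real gene names or the condition
ontology, correlation between evidence class and degree, reference–
interaction clustering by publication type, and TF→TF regulatory layers in
the background graph (cross-TF edges enter only via planted motifs). Passing
tests therefore validate the machinery, not any biological claim about real
networks.

## Pipeline determinism

All seeds are explicit (no wall-clock seeding); every table is emitted in
sorted order with fixed float formatting, JSON is key-sorted, and no output
embeds a timestamp or absolute path. The manifest keys the bundle by a
SHA-256 of the canonical configuration with the output directory excluded
(a destination is not an analysis parameter), so identical configurations
yield byte-identical bundles wherever they are written.

## Problem sizes and limitations

Desk-scale defaults: synthetic networks of 150 TFs × 2000 genes (≈ 5–6 k
interactions) for distribution checks; the planted-motif benchmark uses a
sparse background (8 TFs × 40 genes) plus 30 vertex-disjoint feed-forward
loops — about 140 nodes — profiled at R = 200 over 40 replicates; census
oracle cross-checks run on random digraphs of up to 40 nodes. The published
genome-scale analyses are reproduced only in their printed arithmetic
(densities, partitions, overlaps, shares); curve shapes and genome-scale
motif profiles require the external database download, which does not ship.
The census is O(edges·max-degree) via the fast triadic census and is not
meant for networks beyond ~10⁵ edges with large ensembles on one core.
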