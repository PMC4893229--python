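# Methods

This note records the model, the conventions chosen where a convention was
needed, the design of the synthetic-data generator, and the limits of what
the test suite demonstrates.

## Score normalization

Raw bit scores are symmetrized by taking the maximum over both hit
directions and over duplicate lines; BLAST's asymmetry between `q→s` and
`s→q` is an artifact of seeding and composition, and the maximum is the
conservative, homology-friendly completion. The normalized score is
`s(g1,g2) / max(s(g1,g1), s(g2,g2))`, clamped to [0, 1]. A gene with pair
hits but no self hit falls back to its maximum observed raw score as self
score (warning emitted); this keeps the gene in the analysis rather than
silently dropping it, at the cost of a slightly inflated normalized score.

## Neighborhood Correlation

NC is the Pearson correlation of two genes' zero-filled score vectors over
the full database universe of size `N` (query plus reference genes). Missing
hits are genuine zeros, not missing data: the equation sums over all `N`
database sequences. The sparse implementation corrects the means and
variances for implicit zeros analytically and is required by the test suite
to match a dense zero-filled computation to 1e-10 on instances up to 50
genes.

Conventions:

* Self entries `S(g,g) = 1` are included in the vectors — they are database
  sequences like any other. This choice slightly raises the correlation of
  any two genes that both have self hits; it is applied uniformly, so
  relative ordering is unaffected.
* A zero-variance vector (gene similar to nothing, or uniformly similar to
  everything) yields NC = 0 rather than NaN: a gene with no contrast carries
  no correlation signal, and 0 is neutral downstream.
* NC is evaluated per similarity hit, never for all `N²` pairs; the retention
  floor defaults to 0.05, the conventional threshold for NC-only homology
  pipelines.

## Synteny scores

Neighborhoods are the up-to-`2k` genes at index distance 1..k on the gene's
contig, with `k = 5` by default — the radius repeatedly found adequate for
local synteny in metazoan-scale data. Strand is ignored; only linear order
matters. Neighborhoods exclude the query gene itself; the members of a
candidate pair are *not* excluded from each other's neighborhoods by default
(the definition does not exclude them), but `SyntenyParams(exclude_query_pair=True)`
allows the stricter variant for sensitivity analysis.

`SyS` is the maximum NC over the Cartesian product of two neighborhoods;
an empty neighborhood or the absence of any NC edge gives 0. `SyC` is the
Pearson correlation of the two genes' SyS vectors over their shared NC-hit
set `H`; membership in `ncHits` uses `NC ≥ β` (inclusive) while
candidate-pair selection uses `NC > β` (strict) — both comparisons exactly
as defined. When `|H| < 2` or either vector is constant the correlation is
undefined and SyC is set to 0, the neutral value under the decision
boundary. The same `k` is used for the SyS values inside SyC vectors as for
direct SyS (the definitions do not distinguish them). SyS values are
memoized across pairs; memoized and direct computations are required to
agree exactly.

Genes present in the similarity data but absent from the gene-order
annotation cannot support synteny; they are skipped as candidate pairs and
excluded from `H`.

## Decision boundary

`h = NC² + 0.25·SyC² − 0.25`, homolog iff `h > 0` (strict: a pair exactly on
the boundary is not called). The constants are configurable but
default-locked to the published rule; no refitting is in scope. The zero set
is the ellipse `NC² + 0.25·SyC² = 0.25`, so with SyC = 0 the rule
degenerates to `|NC| > 0.5`. Note a known quirk of the second published
case study: the printed score (0.045) for NC = 0.411, SyC = 0.672 differs
from what the printed formula yields (0.032) — presumably unrounded inputs
were used upstream. This implementation follows the formula; the
discrepancy is documented here rather than reconciled.

Pairs never evaluated by the synteny stage (NC ≤ β) are *absent* from the
homology graph rather than auto-negative, so similarity-only baselines can
still be built from the same NC graph.

## Clustering

All scores are similarities, so clusters merge while the best inter-cluster
linkage is `≥ τ`. Missing cross edges count as similarity 0 — sparse graphs
need a defined completion and 0 is "no detectable similarity". Single
linkage at `τ` is exactly the connected components of the `weight ≥ τ`
subgraph (computed via networkx; an independent union-find oracle checks it
in the tests). Average and complete linkage are implemented directly with
Lance–Williams updates on the zero-completed similarity matrix, because the
similarity-threshold stopping rule and the zero completion are not the
semantics of standard condensed-distance linkage routines. Ties between
equal-linkage merge candidates are broken by the lexicographically least
smallest member id, making every run reproducible. The dense matrix limits
the agglomerative modes to desk-scale inputs (thousands of genes), which is
their intended use here.

Weight-source semantics: `nc` clusters all NC edges; `gfc` clusters only
pairs called homologous, weighted by their NC, which keeps both methods'
thresholds on the same scale so τ sweeps are directly comparable; `bits`
clusters normalized bit scores; `h` uses the decision value itself.

## Evaluation

Per-family quality is the F-score of the best-matching cluster (precision =
overlap/cluster size, recall = overlap/family size). Published descriptions
of which index is "cluster" and which "family" are inconsistent between
formula and prose; the set definitions above are the ones implemented. The
aggregate is reported both member-weighted (weights = gold family sizes) and
unweighted, because the aggregation convention behind published summary
numbers is not derivable; the weighted variant is the primary one used in
tests.

Pair statistics treat a partition over `n` genes as a yes/no labeling of all
`n(n−1)/2` unordered pairs. Mutual information uses natural logarithms and
the standard sign convention (−Σ p ln p); a published rendering of the
entropy without the minus sign is treated as a typo. When two partitions
cover different gene sets, pair statistics are computed on the intersection.
Cluster coherence, by contrast, takes the other method's clusters whole: a
cluster is `common` (identical), `subset` (strictly inside one), `superset`
(a disjoint union of two or more whole clusters) or `contradictory`
(anything else, including members the other method never clustered).

Jaccard over two empty pair sets is defined as 1.0 (flagged with a warning):
two methods that both call nothing agree.

## Reconciliation

Rooted binary gene trees are reconciled with a rooted binary species tree by
LCA mapping; non-binary input (including a trifurcating root, the usual sign
of an unrooted tree) is rejected rather than auto-rooted, because the most
parsimonious reconciliation depends on the root. A gene node is a
duplication exactly when its image equals a child's image. Losses follow
the standard most-parsimonious convention — per gene-tree edge, the number
of species-tree edges between the two images, minus one when the parent is a
speciation — and losses above the gene-tree root are not counted. The LCA
map minimizes duplications and losses simultaneously, which the tests verify
against exhaustive enumeration of all valid mappings on small trees.
Species are extracted from leaf labels by a configurable function (default:
prefix before the first underscore). Clusters below 4 genes are skipped in
aggregate scoring: their trees always score 0 and would only dilute the
per-gene ratio. Weights default to 1.5 per duplication and 1.0 per loss.

## Synthetic-data generator

The generator's purpose is to put every pipeline stage under known ground
truth at desk scale, emulating the structure of full genome-evolution
simulations without sequence-level machinery.

**What is modelled.** Genes evolve along a rooted ultrametric species tree
(default: 6 taxa, height 1.0) by a Gillespie birth–death-translocation
process: per gene and unit time, duplications (tandem with probability
`p_tandem = 0.5`, matching the observation that tandem copies keep their
neighborhood while retrotransposed copies do not, else inserted uniformly),
losses, and translocations to a uniform position. Pairwise similarity of two
same-family genes is `exp(−divergence_rate · t)` with `t` the total lineage
time separating them (tracked exactly through the copy genealogy), perturbed
by multiplicative log-normal noise (σ = 0.1) and truncated to 0 below a
detection floor of 0.05 normalized score, emulating alignment non-hits.

**What is deliberately not modelled.** Actual sequences, indel processes,
codon models, fission/fusion and neofunctionalization (also zeroed in the
reference simulations). Similarity decay replaces substitution because the
pipeline only ever consumes scores: the identical code paths are exercised
at a fraction of the cost. Consequently the generator cannot reproduce
alignment-specific pathologies (compositional bias, local-alignment length
effects); it represents them summarily through two confounders:

* *Spurious hits*: each gene draws a Poisson number (`spurious_hit_rate`) of
  random non-family partners with weak scores, U(0.05, 0.35) — the stand-in
  for chance alignments and low-complexity similarity.
* *Promiscuous domain*: a fraction of families shares a "domain"; carrier
  genes get moderate cross-family scores (`domain_scale` times per-gene
  strengths) — the stand-in for multidomain architecture.

Both default to off; the six regime presets switch them on, because they are
what makes similarity-only inference genuinely fallible.

**Regime presets.** Six presets form the 2×3 design of divergence
(high/low, rates 1.2 and 0.86 — the 350:250 ratio of the substitution-rate
tiers they emulate) by gene-order conservation (translocation rates
0.7/0.35/0.07 in the high-divergence tier, 0.5/0.25/0.05 in the low one —
the printed translocation-rate grid times the tier's substitution budget).
Duplication = loss rates (0.15/0.15/0.15/0.27/0.18/0.18, proportional to the
printed duplication-rate pattern) keep the expected gene count near the
ancestral count (a critical birth–death process, `E[N_t] = N_0`, which the
tests check against the analytic expectation). The divergence scale was
calibrated once, against the qualitative regime targets — distant-ortholog
similarity near the detection floor in the high tier; spurious-edge NC
spread over (0.05, ~0.5) so that no threshold separates it from divergent
true pairs; true-pair SyC clearly positive — and not revisited. Desk scale
is ~50 ancestral genes over 6 species (~300 extant genes); full-scale runs
only need larger `n_ancestral_genes` and a bigger species tree.

**What passing tests show and do not show.** On these synthetic regimes the
synteny-aware pipeline beats similarity-only clustering because the
generator plants exactly the two confounders synteny can detect. Real data
add failure modes the generator does not represent (assembly fragmentation,
annotation errors, segmental duplications of whole neighborhoods, lineage
rate variation), so the benchmark trend is evidence of correct mechanism,
not a measured real-data effect size.

## Pipeline and numerics

Every stage writes TSV with scores at 6 decimals and the next stage consumes
the written file, so results are identical whether a stage was recomputed or
skipped (stage skipping is keyed on SHA-256 of inputs plus parameters).
Reruns with unchanged inputs leave outputs untouched. All randomness flows
from one integer seed through a single PCG64 generator with integer-state
iteration, so fixed seeds reproduce datasets bitwise across platforms.
Correlations are clamped to [−1, 1] against float drift; variance terms
below 1e-12 (relative) are treated as degenerate.

## Known limitations

* The dense agglomerative-linkage implementation is quadratic in memory;
  genome-scale average/complete linkage would need a sparsity-aware rewrite.
* `synteny_all` memoizes SyS per run; very dense NC graphs (β near −1) can
  make the SyC stage expensive.
* Reconciliation handles binary rooted trees only; no rearrangement mode,
  bootstrap awareness, or transfer events.
* Isoform collapsing (one protein per gene) is assumed done upstream.
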