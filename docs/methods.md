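# Methods

## Membrane propensity

For a protein *P* of length *n* the membrane-propensity score is the mean
per-residue transmembrane tendency

    H = (1/n) Σ_{j=1..n} h_j ,

where *h_j* is the propensity of the *j*-th residue under a 20-residue scale.
The shipped default is the transmembrane tendency scale of Zhao & London
(2006, *Protein Science* 15:1987–2001), on which typical soluble sequences
average below zero and TM helices well above it; any user scale covering the
20 canonical residues is accepted. Ambiguous residues (X/B/Z/U/O) are skipped
by default (counted and logged) rather than being assigned invented values;
a strict `error` policy is available. When core-helix intervals are supplied
only those residues are scored; otherwise the full sequence is scored and the
result flagged full-length — core-helix delineation requires structural
analysis outside this package's scope.

Families are classified TM vs soluble by comparing a per-family statistic
(default: median, matching boxplot-style summaries; mean available) against a
boundary (default 0.0 on the shipped scale, whose construction centres the
TM/soluble transition near zero). Exact ties go to soluble and are logged, which
makes classification monotone in the boundary.

Score distributions across families are compared with the Kruskal–Wallis
test (mid-ranks, tie-corrected, chi-square approximation with k−1 df; all-equal
data is rejected as degenerate because the tie correction annihilates the
variance). Pairwise follow-up uses Dunn's z-tests on mean-rank differences
with the tie-corrected pooled variance N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided
normal p-values, and Bonferroni adjustment p_adj = min(1, p·k(k−1)/2). The
critical-difference grouping is the partition induced by connecting every pair
with p_adj ≥ α: families in different components differ significantly at α.

## Phyletic spread and depth

For clade *i* across *M* lineages with *n_j* species of lineage *j* carrying
the clade and *N_j* species sampled:

    S_i = m_i / M,          m_i = |{ j : n_j > 0 }|
    D_i = Σ n_j / Σ N_j     (sums over all M lineages)

Both are kept as exact rationals. Conventions: *n_j* counts species, so
paralogs within one species do not inflate it, and the mediant D sums over
all examined lineages including absent ones (its printed bounds are
j = 1..M). D therefore lies between the extreme per-lineage occupancies and is
invariant to splitting a lineage record into parts with the same totals. The
bar encoding exports width = S and height = D per clade.

## Profile-similarity network and Leiden communities

Pairwise profile-profile comparison records (query, target, p, e) become an
undirected graph on families with edge weight −log10(p). Reciprocal records
for one unordered pair are combined — default `max_weight` keeps the best
(minimum) p, `mean_weight` takes the geometric mean — and pairs with combined
p above a threshold (default 0.05) contribute nodes but no edge. p-values are
the default edge currency; e-values ride along in the records. Zero or
underflowed p is floored at 1e−300 with a warning so weights stay finite.

Sub-networks are detected with the Leiden algorithm (leidenalg/igraph) on the
weighted graph: default quality is modularity in its resolution-parametrized
(RB) form at resolution 1.0, CPM available; 20 restarts with consecutive
seeds are run and the best partition by quality kept, making the result
deterministic given (seed, n_restarts). Recovery in tests is quantified with
the adjusted Rand index.

## Contextual networks and enrichment

Domain architectures (ordered domain hits of one product, by aa_start) and
gene neighborhoods are decomposed into ordered domain runs. A neighborhood is
a maximal run of consecutive genes on one contig with intergenic gaps ≤
`max_gap_bp` (default 200 bp) and, under the default `same_strand` rule, a
shared strand — standard operon-context heuristics, all configurable.
`max_genes` (default 7) caps a run at that many genes per side of a gene
carrying the focal domain; focal-free runs longer than the 15-gene window are
truncated with a log note. Minus-strand signatures are reversed so that a
neighborhood reads the same regardless of encoding strand. A separate
`filter_conserved` operation keeps neighborhoods whose signature recurs in ≥ k
genomes (default 3); it is opt-in (`--conserved-only` in the CLI) because
signature-level recurrence is a proxy for the sequence-clustering-based
conservation analysis that full pipelines run upstream, and it is deliberately
not part of the planted-signal analysis path, whose neighborhoods vary freely.

Consecutive domains within an instance become edges of the contextual graph;
`support` counts distinct contributing genomes, repeat-domain self-adjacencies
are dropped, and edges below `min_support` are removed while their endpoint
domains remain as nodes. The recommended support threshold is recurrence in
≥ 7.5% of genomes (at least 2): at the default simulation geometry a planted
focal–partner adjacency recurs in roughly a quarter of genomes while a
sporadic juxtaposition recurs in ~1–2%, so the threshold sits far from both
(about +6σ from the sporadic mean and −6σ from the planted one under Poisson
counts).

All maximal cliques containing the focal domain are enumerated with pivoting
Bron–Kerbosch restricted to the focal node's closed neighborhood (the two
clique sets provably coincide) and merged — node union, within-clique edge
union — into the focal dense subgraph. The minimum clique size defaults to 3:
with min_size = 2 the merge is exactly the induced ego graph of the focal
node, an identity the tests exploit as an oracle.

Per functional category, a 2×2 table counts labeled vs other domains inside
the dense subgraph (focal excluded) against the background of graph nodes
outside it; unlabeled domains count as "other". The one-sided (greater)
Fisher exact p is the hypergeometric upper tail P(X ≥ a), accumulated by
exact term summation in log space with cached log-factorials (agrees with
integer enumeration to ~1e−13 over all margins N ≤ 40). Benjamini–Hochberg
correction across categories (α = 0.05 default) flags significant
enrichments; Bonferroni-style conservatism can be had by lowering α.
Counting is node-level, matching a graph whose nodes are domains.

## Synthetic data: what is emulated, and what is not

The generators emulate the statistical structure of the study inputs, not
their biology:

- **Family sequences.** Residues are a two-residue Bernoulli mixture of the
  active scale's most hydrophobic and most hydrophilic residues (F and K on
  the shipped scale), with the mixture weight solving the target mean in
  closed form; per-sequence targets are drawn N(target, tm_sd) truncated to
  the scale range. The default superfamily layout is 30 families × 20
  sequences × 150 aa, 18 families at target +1.0 (TM-like) and 12 at −1.0
  (soluble-like), sd 0.15 — score separations comparable to real TM vs
  soluble families on this scale. No real composition, motifs or evolution
  are simulated; passing tests show the scoring/classification machinery is
  correct, not that the scale separates any particular real family.
- **Phyletic profiles.** Occupied-lineage count = round(S·M) (so recovered S
  is within 1/(2M)); total presence = nearest feasible integer to round(D·ΣN_j)
  distributed one-per-occupied-lineage then round-robin. Defaults M = 20
  lineages, N_j = 10 species. Infeasible (S, D) pairs raise an error listing
  the feasible depth range.
- **Comparison tables.** Within-community pairs draw p = 10^(−U(5, 20));
  between-community pairs draw p ~ U(0.05, 1), both directions independently
  (profile-profile searches are not symmetric). Default layout: 4 communities
  × 10 families. At the default 0.05 edge threshold the planted blocks are
  cleanly separable; community detection still has to resolve them from the
  weighted graph.
- **Context datasets.** Each genome carries 3 tandem same-strand gene blocks
  of 4–8 genes (900 bp genes, 50 bp intra-block gaps, 5 kb between blocks);
  one block contains the focal domain at a random slot. Non-focal slots draw
  an enriched-category domain with probability 0.8 in the focal block and 0.2
  elsewhere, otherwise a uniform background domain. The default pool has 6
  enriched-category and 24 background domains, so the neutral composition is
  6/30 = 0.2: the background rate reproduces neutral composition, and setting
  both rates to 0.2 yields a fully domain-exchangeable null on which Fisher's
  conditioning is valid. Defaults: 200 genomes. Gene order within blocks,
  real operon architecture and genome rearrangement are not modeled.

All draws flow from one integer seed through per-stage
`numpy.random.default_rng` substreams; identical seeds give byte-identical
outputs, which the CLI tests assert file-by-file.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run entirely on generated data at
desk scale: 1000-sequence scoring oracles, all 135,750 Fisher tables with
N ≤ 40 (max deviation from exact integer enumeration ~6e−14), 200 random
graphs (≤ 13 nodes) against exhaustive clique enumeration, 100-seed Leiden
recovery, and 25–200 replicate enrichment simulations at 200 genomes. The
acceptance script reports recovery rates and oracle errors rather than any
database-derived quantity, since the pipeline's inputs at study scale come
from sequence searches this package deliberately does not perform.

Known limitations: Dunn p-values rely on the normal approximation (checked
against a permutation oracle within Monte-Carlo error); Leiden restarts
mitigate but cannot abolish local optima on marginal graphs; the conserved-
adjacency support threshold is geometry-dependent and should be revisited for
datasets whose neighborhood count per genome differs greatly from the
simulated three.
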