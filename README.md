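# superfam

Comparative-genomics characterization of protein superfamilies. The package
implements the computational arms used to characterize a newly delineated
superfamily of membrane-associated enzymatic domains acting on lipid head
groups: scoring how membrane-like each family's sequences are, quantifying
how widely and deeply each clade is conserved across the tree of life,
grouping families into higher-order assemblages from profile–profile
comparison scores, and mining gene neighborhoods and domain architectures
for statistically enriched functional partners. It is aimed at
computational biologists who already have search results (profile
comparisons, domain annotations, gene coordinates) and need the downstream
statistics, plus a synthetic-data module that generates every input class
with planted ground truth for validation.

## What it computes

- **Membrane propensity** — per-protein score `H = (1/n) Σ h_j` under a
  20-residue transmembrane tendency scale (Zhao & London 2006 shipped as the
  default), per-family TM/soluble classification against a boundary, and a
  Kruskal–Wallis omnibus test with Dunn's post-hoc pairwise z-tests
  (Bonferroni-corrected) plus critical-difference grouping.
- **Phyletic metrics** — spread `S = m/M` (fraction of lineages with ≥ 1
  representative) and depth `D = Σn_j / ΣN_j`, the mediant of per-lineage
  species occupancies, with the bar encoding width = S, height = D.
- **Similarity network** — families as nodes, edge weight `−log10 p` from
  profile–profile comparisons, Leiden community detection (modularity or
  CPM, seeded restarts) and adjusted-Rand agreement.
- **Contextual network** — domain architectures and gene neighborhoods
  decomposed into domain-adjacency graphs; all maximal cliques containing a
  focal domain merged into its dense subgraph; per-category one-sided Fisher
  exact enrichment with Benjamini–Hochberg correction.

## Worked example

Generate a synthetic study (30 families, 18 of them TM-propense; 4 planted
network communities; 200 genomes with a lipid-enriched focal neighborhood),
then run the propensity and context arms:

```sh
superfam --seed 7 --out-dir demo simulate
superfam --seed 7 --out-dir demo/tm tmscore \
    --fasta demo/sequences.fasta --families demo/families.tsv
superfam --seed 7 --out-dir demo/cx context \
    --genes demo/genes.tsv --domains demo/domains.tsv \
    --labels demo/labels.yaml --focal Lipocone
```

The `tmscore` run logs

```
Kruskal-Wallis H=439.6 p=6.791e-75; 18 TM / 30 families
```

i.e. the 18 planted membrane-propense families are classified TM (median
score above the 0.0 boundary) and the omnibus test overwhelmingly rejects
homogeneity of score distributions across families. The `context` run logs
`graph: 31 domains, 21 edges; dense subgraph: 7 domains; 1 significant
category(ies)` and `demo/cx/enrichment.tsv` begins

```
focal_domain  category  a  b  c  d  odds_ratio  p_value   q_value   significant
Lipocone      lipid     6  0  0  24 inf         1.68e-06  6.74e-06  True
```

all six lipid-metabolism domains (a = 6) sit inside the focal dense
subgraph and none of the 24 background domains do (c = 0), so the planted
lipid enrichment is recovered at q ≈ 7e−6.

The same operations are importable (`superfam.sequence_tm_score`,
`superfam.phyletic_depth`, `superfam.detect_communities`,
`superfam.dense_subgraph`, `superfam.test_enrichment`, …) for notebook use.

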