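"""Contextual (gene-neighborhood / domain-architecture) network analysis.

Domain architectures and gene neighborhoods are decomposed into ordered runs
of domains; consecutive domains become edges of a contextual graph whose
nodes are domain names and whose edge support counts contributing genomes.
All maximal cliques containing a focal domain are merged into its dense
subgraph, and functional-category over-representation in that subgraph
relative to the rest of the graph is tested with a one-sided Fisher exact
test, Benjamini–Hochberg corrected across categories.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import DomainHit, FunctionalLabelMap, GeneRecord

logger = logging.getLogger("superfam.context")


@dataclass(frozen=True)
class ContextInstance:
    """One decomposed context: a domain architecture or a gene neighborhood.

    ``occurrences`` are (domain_name, gene_id, position) ordered by
    coordinate; ``signature`` is the strand-normalized ordered domain string.
    """

    kind: str  # "architecture" | "neighborhood"
    genome_id: str
    occurrences: tuple[tuple[str, str, int], ...]
    signature: str

    def __post_init__(self) -> None:
        if self.kind not in ("architecture", "neighborhood"):
            raise ValidationError(f"unknown context kind {self.kind!r}")
        if not self.occurrences:
            raise ValidationError("context instance with no domain occurrences")

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(occ[0] for occ in self.occurrences)


@dataclass(frozen=True)
class DenseSubgraph:
    """Union of all qualifying cliques containing the focal domain."""

    focal_domain: str
    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]
    cliques: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class EnrichmentResult:
    focal_domain: str
    category: str
    a: int  # labeled, in subgraph (focal excluded)
    b: int  # other, in subgraph
    c: int  # labeled, in background
    d: int  # other, in background
    odds_ratio: float
    p_value: float
    q_value: float
    significant: bool


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _signature(domains: Sequence[str], strand: str) -> str:
    ordered = list(domains) if strand != "-" else list(reversed(domains))
    return "|".join(ordered)


def decompose_contexts(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    max_gap_bp: int = 200,
    max_genes: int = 7,
    strand_rule: str = "same_strand",
    focal_domain: str | None = None,
) -> list[ContextInstance]:
    """Decompose architectures and neighborhoods into ordered domain runs.

    Architectures: one instance per multi-domain product, domains ordered by
    aa_start.  Neighborhoods: maximal runs of consecutive genes on one contig
    with intergenic gaps <= ``max_gap_bp`` (and, under ``same_strand``, a
    shared strand).  ``max_genes`` caps a neighborhood at that many genes per
    side of a gene carrying ``focal_domain``; runs longer than the 2 x
    max_genes + 1 window with no focal gene are truncated to the window (with
    a log note).  Deterministic given inputs.
    """
    if max_gap_bp < 0:
        raise ParameterError("max_gap_bp must be >= 0")
    if max_genes < 2:
        raise ParameterError("max_genes must be >= 2")
    if strand_rule not in ("same_strand", "any_strand"):
        raise ParameterError(f"unknown strand_rule {strand_rule!r}")

    known_products = {g.product_id for g in genes}
    hits_by_product: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.product_id not in known_products:
            raise ValidationError(
                f"domain hit references unknown product {hit.product_id!r}"
            )
        hits_by_product.setdefault(hit.product_id, []).append(hit)
    for product in hits_by_product:
        hits_by_product[product].sort(key=lambda h: (h.aa_start, h.aa_end, h.domain_name))

    genome_of = {g.product_id: g.genome_id for g in genes}
    instances: list[ContextInstance] = []

    # architectures: ordered domain string of each product
    for product in sorted(hits_by_product):
        prod_hits = hits_by_product[product]
        if len(prod_hits) < 2:
            continue  # single-domain products contribute no intra-product adjacency
        domains = tuple(h.domain_name for h in prod_hits)
        instances.append(ContextInstance(
            kind="architecture",
            genome_id=genome_of[product],
            occurrences=tuple((d, product, i) for i, d in enumerate(domains)),
            signature=_signature(domains, "+"),
        ))

    # neighborhoods: maximal gene runs per contig under gap/strand rules
    ordered = sorted(genes, key=lambda g: (g.genome_id, g.contig_id, g.start, g.gene_id))
    window = 2 * max_genes + 1
    for (_genome, _contig), contig_genes in itertools.groupby(
            ordered, key=lambda g: (g.genome_id, g.contig_id)):
        contig_genes = list(contig_genes)
        run: list[GeneRecord] = []
        for gene in contig_genes:
            if run:
                gap = gene.start - run[-1].end - 1
                same_strand_ok = strand_rule == "any_strand" or gene.strand == run[-1].strand
                if gap > max_gap_bp or not same_strand_ok:
                    instances.extend(
                        _emit_neighborhoods(run, hits_by_product, window, focal_domain)
                    )
                    run = []
            run.append(gene)
        if run:
            instances.extend(_emit_neighborhoods(run, hits_by_product, window, focal_domain))
    return instances


def _gene_domains(gene: GeneRecord,
                  hits_by_product: dict[str, list[DomainHit]]) -> list[str]:
    ordered = hits_by_product.get(gene.product_id, [])
    if gene.strand == "-":
        ordered = list(reversed(ordered))
    return [h.domain_name for h in ordered]


def _run_to_instance(run: Sequence[GeneRecord],
                     hits_by_product: dict[str, list[DomainHit]]
                     ) -> ContextInstance | None:
    occurrences = []
    pos = 0
    for gene in run:
        for domain in _gene_domains(gene, hits_by_product):
            occurrences.append((domain, gene.gene_id, pos))
            pos += 1
    if not occurrences:
        return None
    strand = run[0].strand
    return ContextInstance(
        kind="neighborhood",
        genome_id=run[0].genome_id,
        occurrences=tuple(occurrences),
        signature=_signature([o[0] for o in occurrences], strand),
    )


def _emit_neighborhoods(run: Sequence[GeneRecord],
                        hits_by_product: dict[str, list[DomainHit]],
                        window: int,
                        focal_domain: str | None) -> list[ContextInstance]:
    if len(run) <= window:
        inst = _run_to_instance(run, hits_by_product)
        return [inst] if inst else []
    half = (window - 1) // 2
    if focal_domain is not None:
        focal_idx = [
            i for i, gene in enumerate(run)
            if focal_domain in _gene_domains(gene, hits_by_product)
        ]
        if focal_idx:
            out = []
            for i in focal_idx:
                lo = max(0, i - half)
                hi = min(len(run), i + half + 1)
                inst = _run_to_instance(run[lo:hi], hits_by_product)
                if inst:
                    out.append(inst)
            return out
    logger.info("run of %d genes exceeds %d-gene window with no focal gene; truncated",
                len(run), window)
    inst = _run_to_instance(run[:window], hits_by_product)
    return [inst] if inst else []


def filter_conserved(instances: Iterable[ContextInstance],
                     min_genomes: int = 3) -> list[ContextInstance]:
    """Keep neighborhood instances whose signature occurs in >= min_genomes
    distinct genomes (architectures are kept unconditionally)."""
    instances = list(instances)
    genomes_per_sig: dict[str, set[str]] = {}
    for inst in instances:
        if inst.kind == "neighborhood":
            genomes_per_sig.setdefault(inst.signature, set()).add(inst.genome_id)
    return [
        inst for inst in instances
        if inst.kind == "architecture"
        or len(genomes_per_sig[inst.signature]) >= min_genomes
    ]


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_context_graph(instances: Sequence[ContextInstance],
                        min_support: int = 1) -> nx.Graph:
    """Contextual graph: domain nodes, consecutive-pair edges.

    Edge ``support`` counts distinct genomes contributing the adjacency; a
    ``kind`` attribute records which context types contributed.  Repeat-domain
    self-adjacencies are dropped (and logged).  Edges below ``min_support``
    are removed; their endpoint nodes are retained.
    """
    if not instances:
        raise ValidationError("no context instances supplied")
    graph = nx.Graph()
    support: dict[frozenset[str], set[str]] = {}
    kinds: dict[frozenset[str], set[str]] = {}
    n_self = 0
    for inst in instances:
        domains = inst.domains
        graph.add_nodes_from(domains)
        for a, b in zip(domains, domains[1:]):
            if a == b:
                n_self += 1
                continue
            key = frozenset((a, b))
            support.setdefault(key, set()).add(inst.genome_id)
            kinds.setdefault(key, set()).add(inst.kind)
    if n_self:
        logger.info("dropped %d repeat-domain self-adjacency(ies)", n_self)
    for key, genomes in support.items():
        if len(genomes) < min_support:
            continue
        a, b = sorted(key)
        graph.add_edge(a, b, support=len(genomes),
                       kind=",".join(sorted(kinds[key])))
    return graph


# ---------------------------------------------------------------------------
# cliques and the dense subgraph
# ---------------------------------------------------------------------------

def enumerate_focal_cliques(graph: nx.Graph, focal: str,
                            min_size: int = 3) -> list[frozenset[str]]:
    """All maximal cliques containing ``focal`` with size >= min_size.

    Uses pivoting Bron–Kerbosch (networkx) restricted to the closed
    neighborhood of the focal node; maximal cliques of that induced subgraph
    that contain the focal node are exactly the maximal cliques of the full
    graph containing it.
    """
    if focal not in graph:
        raise ValidationError(f"focal domain {focal!r} absent from graph")
    if min_size < 2:
        raise ParameterError("min_size must be >= 2")
    closed = set(graph.neighbors(focal)) | {focal}
    sub = graph.subgraph(closed)
    cliques = [
        frozenset(c) for c in nx.find_cliques(sub)
        if focal in c and len(c) >= min_size
    ]
    return sorted(cliques, key=lambda c: (len(c), sorted(c)))


def merge_focal_cliques(cliques: Sequence[frozenset[str]], graph: nx.Graph,
                        focal: str) -> DenseSubgraph:
    """Union of clique node sets and within-clique edges; the dense subgraph.

    With no qualifying cliques the subgraph degenerates to the focal node
    alone (warned).  With min_size=2 upstream, the merge provably equals the
    induced subgraph on the focal node's closed neighborhood.
    """
    if focal not in graph:
        raise ValidationError(f"focal domain {focal!r} absent from graph")
    for clique in cliques:
        if focal not in clique:
            raise ValidationError(f"clique {sorted(clique)} does not contain focal {focal!r}")
    if not cliques:
        logger.warning("no cliques for focal %r; dense subgraph is the focal node alone",
                       focal)
        return DenseSubgraph(focal_domain=focal, nodes=frozenset({focal}),
                             edges=frozenset(), cliques=())
    nodes = frozenset().union(*cliques)
    edges = frozenset(
        frozenset(pair)
        for clique in cliques
        for pair in itertools.combinations(sorted(clique), 2)
    )
    return DenseSubgraph(focal_domain=focal, nodes=nodes, edges=edges,
                         cliques=tuple(cliques))


def dense_subgraph(graph: nx.Graph, focal: str,
                   min_size: int = 3) -> DenseSubgraph:
    """Convenience: enumerate focal cliques then merge them."""
    return merge_focal_cliques(
        enumerate_focal_cliques(graph, focal, min_size=min_size), graph, focal
    )


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

_LOGFACT = np.array([0.0])


def _logfact(n: int) -> np.ndarray:
    """log(k!) for k = 0..n, cached and grown on demand."""
    global _LOGFACT
    if n >= _LOGFACT.size:
        _LOGFACT = gammaln(np.arange(max(n + 1, 2 * _LOGFACT.size)) + 1.0)
    return _LOGFACT


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The hypergeometric upper tail P(X >= a) for X ~ Hypergeom(N=a+b+c+d,
    K=a+c, n=a+b) is accumulated by exact term summation in log space.
    """
    counts = (a, b, c, d)
    if any(int(x) != x for x in counts) or any(x < 0 for x in counts):
        raise ValidationError(f"contingency counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    N = a + b + c + d
    K = a + c
    n = a + b
    if N == 0:
        return 1.0
    lf = _logfact(N)
    lo = max(0, n + K - N)
    hi = min(K, n)
    if a <= lo:
        return 1.0
    ks = np.arange(a, hi + 1)
    # log C(K, k) + log C(N-K, n-k) - log C(N, n)
    log_terms = (
        lf[K] - lf[ks] - lf[K - ks]
        + lf[N - K] - lf[n - ks] - lf[N - K - (n - ks)]
        - (lf[N] - lf[n] - lf[N - n])
    )
    peak = log_terms.max()
    tail = math.exp(peak) * float(np.exp(log_terms - peak).sum())
    return min(1.0, tail)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_enrichment(subgraph: DenseSubgraph, graph: nx.Graph,
                    labels: FunctionalLabelMap,
                    alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-category over-representation of the dense subgraph vs background.

    For each vocabulary category with >= 1 labeled node in the graph:
    a/b count labeled/other nodes inside the subgraph (focal excluded) and
    c/d the same over the background (graph nodes outside the subgraph);
    unlabeled nodes count as "other".  One-sided Fisher p per category, BH q
    across categories, flagged significant at q <= alpha.
    """
    if not set(subgraph.nodes) <= set(graph.nodes):
        raise ValidationError("dense subgraph contains nodes absent from the graph")
    inside = set(subgraph.nodes) - {subgraph.focal_domain}
    outside = set(graph.nodes) - set(subgraph.nodes)
    categories = [
        cat for cat in labels.vocabulary
        if any(labels.category_of(node) == cat
               for node in set(graph.nodes) - {subgraph.focal_domain})
    ]
    if not categories:
        raise ValidationError("label map covers no category present in the graph")
    rows = []
    for cat in categories:
        a = sum(1 for node in inside if labels.category_of(node) == cat)
        b = len(inside) - a
        c = sum(1 for node in outside if labels.category_of(node) == cat)
        d = len(outside) - c
        if b * c == 0:
            odds = math.inf if a * d > 0 else math.nan
        else:
            odds = (a * d) / (b * c)
        p = fisher_exact_one_sided(a, b, c, d)
        rows.append((cat, a, b, c, d, odds, p))
    qs = bh_adjust([r[6] for r in rows])
    results = [
        EnrichmentResult(
            focal_domain=subgraph.focal_domain, category=cat,
            a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p,
            q_value=float(q), significant=bool(q <= alpha),
        )
        for (cat, a, b, c, d, odds, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


test_enrichment.__test__ = False  # name mimics the statistical usage, not pytest's


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.focal_domain, r.category, r.a, r.b, r.c, r.d, r.odds_ratio,
          r.p_value, r.q_value, r.significant) for r in results],
        columns=["focal_domain", "category", "a", "b", "c", "d",
                 "odds_ratio", "p_value", "q_value", "significant"],
    )
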