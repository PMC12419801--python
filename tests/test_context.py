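"""Context decomposition, clique merging and enrichment statistics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from superfam import (
    ContextSpec,
    DomainHit,
    FunctionalLabelMap,
    GeneRecord,
    ParameterError,
    SimulationSpec,
    ValidationError,
    bh_adjust,
    build_context_graph,
    decompose_contexts,
    dense_subgraph,
    enumerate_focal_cliques,
    filter_conserved,
    fisher_exact_one_sided,
    gen_context_dataset,
    merge_focal_cliques,
    test_enrichment,
)


def gene(gid, start, end, strand="+", genome="g1", contig="c1"):
    return GeneRecord(genome, contig, gid, start, end, strand, f"p_{gid}")


def hit(gid, domain, aa_start=1, aa_end=50):
    return DomainHit(f"p_{gid}", domain, aa_start, aa_end, 10.0, "t")


class TestDecompose:
    def test_multidomain_product_ordered_by_coordinate(self):
        genes = [gene("a", 1, 900)]
        hits = [hit("a", "B", 70, 120), hit("a", "A", 5, 60)]
        (inst,) = [i for i in decompose_contexts(genes, hits)
                   if i.kind == "architecture"]
        assert inst.domains == ("A", "B")

    def test_adjacent_same_strand_genes_form_one_neighborhood(self):
        genes = [gene("a", 1, 900), gene("b", 951, 1850)]  # gap 50
        hits = [hit("a", "A"), hit("b", "B")]
        instances = decompose_contexts(genes, hits, max_gap_bp=200)
        kinds = [i for i in instances if i.kind == "neighborhood"]
        assert len(kinds) == 1 and kinds[0].domains == ("A", "B")

    def test_large_gap_splits_into_singletons(self):
        genes = [gene("a", 1, 900), gene("b", 5901, 6800)]  # gap 5000
        hits = [hit("a", "A"), hit("b", "B")]
        instances = decompose_contexts(genes, hits, max_gap_bp=200)
        assert sorted(i.domains for i in instances) == [("A",), ("B",)]

    def test_gap_exactly_at_threshold_is_kept_together(self):
        genes = [gene("a", 1, 900), gene("b", 1101, 2000)]  # gap 200
        hits = [hit("a", "A"), hit("b", "B")]
        (inst,) = decompose_contexts(genes, hits, max_gap_bp=200)
        assert inst.domains == ("A", "B")

    def test_strand_change_splits_under_same_strand_rule(self):
        genes = [gene("a", 1, 900), gene("b", 951, 1850, strand="-")]
        hits = [hit("a", "A"), hit("b", "B")]
        split = decompose_contexts(genes, hits, strand_rule="same_strand")
        joined = decompose_contexts(genes, hits, strand_rule="any_strand")
        assert sorted(i.domains for i in split) == [("A",), ("B",)]
        assert [i.domains for i in joined] == [("A", "B")]

    def test_minus_strand_signature_is_normalized(self):
        plus = decompose_contexts(
            [gene("a", 1, 900), gene("b", 951, 1850)],
            [hit("a", "A"), hit("b", "B")])
        minus = decompose_contexts(
            [gene("c", 1, 900, strand="-"), gene("d", 951, 1850, strand="-")],
            [hit("c", "B"), hit("d", "A")])
        assert plus[0].signature == minus[0].signature == "A|B"

    def test_unknown_product_rejected(self):
        with pytest.raises(ValidationError, match="unknown product"):
            decompose_contexts([gene("a", 1, 900)],
                               [DomainHit("ghost", "A", 1, 50, 1.0)])

    def test_long_run_windowed_around_focal_gene(self):
        genes = [gene(f"g{i}", 1 + i * 950, 900 + i * 950) for i in range(9)]
        hits = [hit(f"g{i}", "F" if i == 4 else f"D{i}") for i in range(9)]
        (inst,) = decompose_contexts(genes, hits, max_genes=2, focal_domain="F")
        assert inst.domains == ("D2", "D3", "F", "D5", "D6")


class TestConservedFilter:
    def test_recurrent_signatures_kept(self):
        instances = []
        for genome in ("g1", "g2", "g3"):
            genes = [gene("a", 1, 900, genome=genome), gene("b", 951, 1850, genome=genome)]
            hits = [hit("a", "A"), hit("b", "B")]
            instances += [i for i in decompose_contexts(genes, hits)
                          if i.kind == "neighborhood"]
        rare_genes = [gene("x", 1, 900, genome="g4"), gene("y", 951, 1850, genome="g4")]
        rare = [i for i in decompose_contexts(rare_genes, [hit("x", "Q"), hit("y", "R")])
                if i.kind == "neighborhood"]
        kept = filter_conserved(instances + rare, min_genomes=3)
        assert {i.signature for i in kept} == {"A|B"}


class TestContextGraph:
    def test_chain_instance_yields_consecutive_edges(self):
        genes = [gene(g, 1 + i * 950, 900 + i * 950) for i, g in enumerate("abc")]
        hits = [hit("a", "A"), hit("b", "B"), hit("c", "C")]
        graph = build_context_graph(decompose_contexts(genes, hits))
        assert set(map(frozenset, graph.edges)) == {frozenset("AB"), frozenset("BC")}
        assert graph["A"]["B"]["support"] == 1

    def test_support_counts_distinct_genomes(self):
        instances = []
        for genome in ("g1", "g2", "g3"):
            genes = [gene("a", 1, 900, genome=genome), gene("b", 951, 1850, genome=genome)]
            instances += decompose_contexts(genes, [hit("a", "A"), hit("b", "B")])
        graph = build_context_graph(instances, min_support=2)
        assert graph["A"]["B"]["support"] == 3

    def test_self_adjacency_dropped(self):
        genes = [gene("a", 1, 2000)]
        hits = [hit("a", "A", 1, 50), hit("a", "A", 60, 110), hit("a", "B", 120, 170)]
        graph = build_context_graph(decompose_contexts(genes, hits))
        assert not graph.has_edge("A", "A")
        assert graph.has_edge("A", "B")

    def test_low_support_edges_removed_nodes_kept(self):
        genes = [gene("a", 1, 900), gene("b", 951, 1850)]
        graph = build_context_graph(
            decompose_contexts(genes, [hit("a", "A"), hit("b", "B")]),
            min_support=2)
        assert set(graph.nodes) == {"A", "B"} and graph.number_of_edges() == 0


def brute_force_focal_cliques(graph, focal, min_size):
    """Exhaustive maximal-clique enumeration by subset testing (<= 12 nodes)."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            s = set(subset)
            if focal not in s:
                continue
            if all(graph.has_edge(a, b) for a, b in itertools.combinations(s, 2)):
                cliques.append(s)
    maximal = [
        frozenset(c) for c in cliques
        if not any(c < other for other in cliques)
    ]
    return sorted((c for c in maximal if len(c) >= min_size),
                  key=lambda c: (len(c), sorted(c)))


class TestCliques:
    def test_triangle_is_single_clique(self):
        g = nx.Graph([("F", "A"), ("F", "B"), ("A", "B")])
        assert enumerate_focal_cliques(g, "F", min_size=3) == [frozenset("FAB")]

    def test_star_has_no_triangle_cliques(self):
        g = nx.Graph([("F", "A"), ("F", "B")])
        assert enumerate_focal_cliques(g, "F", min_size=3) == []

    def test_missing_focal_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_focal_cliques(nx.Graph([("A", "B")]), "F")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        focal = "n0"
        g.add_node(focal)
        for min_size in (2, 3):
            assert enumerate_focal_cliques(g, focal, min_size) == \
                brute_force_focal_cliques(g, focal, min_size)


class TestMerge:
    def test_union_of_two_cliques(self):
        g = nx.Graph([("F", "A"), ("F", "B"), ("A", "B"),
                      ("F", "C"), ("B", "C")])
        sub = dense_subgraph(g, "F", min_size=3)
        assert sub.nodes == frozenset("FABC")
        assert sub.edges == {frozenset(e) for e in
                             [("F", "A"), ("F", "B"), ("A", "B"),
                              ("F", "C"), ("B", "C")]}

    def test_no_cliques_degenerates_to_focal_singleton(self):
        g = nx.Graph([("F", "A"), ("F", "B")])  # star, no triangle
        sub = dense_subgraph(g, "F", min_size=3)
        assert sub.nodes == frozenset({"F"}) and sub.edges == frozenset()

    def test_clique_without_focal_rejected(self):
        g = nx.Graph([("F", "A"), ("A", "B")])
        with pytest.raises(ValidationError):
            merge_focal_cliques([frozenset("AB")], g, "F")

    @pytest.mark.parametrize("seed", range(10))
    def test_min_size_two_merge_equals_ego_graph(self, seed):
        g = nx.gnp_random_graph(12, 0.35, seed=seed)
        focal = 0
        sub = dense_subgraph(g, focal, min_size=2)
        ego = nx.ego_graph(g, focal)
        if g.degree(focal) == 0:
            assert sub.nodes == frozenset({focal})
            return
        assert sub.nodes == frozenset(ego.nodes)
        assert sub.edges == {frozenset(e) for e in ego.edges}

    @pytest.mark.parametrize("seed", range(10))
    def test_subgraph_within_closed_neighborhood(self, seed):
        g = nx.gnp_random_graph(15, 0.3, seed=seed + 100)
        focal = 0
        sub = dense_subgraph(g, focal, min_size=3)
        closed = set(g.neighbors(focal)) | {focal}
        assert sub.nodes <= closed


class TestFisher:
    def test_a_zero_gives_p_one(self):
        assert fisher_exact_one_sided(0, 5, 3, 7) == 1.0

    def test_hand_enumerated_table(self):
        # margins 4/4 of 8: P(X >= 3) = (16 + 1)/C(8,4) = 17/70
        assert fisher_exact_one_sided(3, 1, 1, 3) == pytest.approx(17 / 70, abs=1e-12)

    def test_matches_scipy_hypergeom_tail(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            expected = stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)
            assert fisher_exact_one_sided(a, b, c, d) == pytest.approx(
                expected, abs=1e-10)

    def test_monotone_decreasing_in_a_with_fixed_margins(self):
        for K, n, N in [(4, 4, 8), (6, 5, 12), (10, 8, 20)]:
            prev = 1.0 + 1e-15
            for a in range(max(0, n + K - N), min(K, n) + 1):
                b, c = n - a, K - a
                d = N - K - b
                if min(b, c, d) < 0:
                    continue
                p = fisher_exact_one_sided(a, b, c, d)
                assert p <= prev + 1e-12
                prev = p

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_one_sided(-1, 2, 3, 4)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestEnrichment:
    def _fixture_graph(self):
        g = nx.Graph([("F", "E1"), ("F", "E2"), ("E1", "E2"),
                      ("B1", "B2"), ("F", "B1")])
        g.add_nodes_from(["B3", "B4"])
        labels = FunctionalLabelMap(
            vocabulary=("lipid", "other_cat"),
            mapping={"E1": "lipid", "E2": "lipid", "B1": "other_cat",
                     "B2": "other_cat", "B3": "other_cat"})
        return g, labels

    def test_extreme_table_ranks_enriched_category_first(self):
        g, labels = self._fixture_graph()
        sub = dense_subgraph(g, "F", min_size=3)  # {F, E1, E2}
        results = test_enrichment(sub, g, labels)
        assert results[0].category == "lipid"
        assert results[0].a == 2 and results[0].b == 0
        assert results[0].p_value < results[-1].p_value

    def test_margins_cover_all_nonfocal_nodes(self):
        g, labels = self._fixture_graph()
        sub = dense_subgraph(g, "F", min_size=3)
        for r in test_enrichment(sub, g, labels):
            assert r.a + r.b + r.c + r.d == len(g) - 1

    def test_unlabeled_nodes_count_as_other(self):
        g, labels = self._fixture_graph()
        sub = dense_subgraph(g, "F", min_size=3)
        lipid = next(r for r in test_enrichment(sub, g, labels)
                     if r.category == "lipid")
        # B4 is unlabeled: it must appear in d
        assert lipid.c + lipid.d == 4

    def test_planted_dataset_recovers_enriched_category(self):
        spec = SimulationSpec(seed=13, contexts=ContextSpec(n_genomes=200))
        genes, hits, labels, _ = gen_context_dataset(spec)
        from superfam import build_context_graph, recommended_min_support

        instances = decompose_contexts(genes, hits, focal_domain="Lipocone")
        graph = build_context_graph(
            instances, min_support=recommended_min_support(200))
        sub = dense_subgraph(graph, "Lipocone", min_size=3)
        results = test_enrichment(sub, graph, labels)
        assert results[0].category == "lipid" and results[0].significant
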