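"""Family-relationship network from profile-profile comparison scores.

Edges carry weight = −log10(p) from pairwise profile-profile comparisons
(e.g. HHalign); reciprocal query/target records for one unordered pair are
combined, pairs above a p-value threshold are dropped, and higher-order
assemblages are detected with the Leiden algorithm on the weighted graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ParameterError, ValidationError

logger = logging.getLogger("superfam.simnet")

P_FLOOR = 1e-300  # zero / underflowed p-values are floored here, with a warning


@dataclass(frozen=True)
class ProfileComparison:
    """One directed profile-profile comparison record."""

    query_family: str
    target_family: str
    p_value: float
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"comparison {self.query_family}->{self.target_family}: "
                f"p_value {self.p_value} outside [0, 1]"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"comparison {self.query_family}->{self.target_family}: "
                f"negative e_value {self.e_value}"
            )


@dataclass(frozen=True)
class SimilarityNetwork:
    """Weighted undirected family graph; weight = −log10(combined p)."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(
            (a, b, d["weight"]) if a <= b else (b, a, d["weight"])
            for a, b, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["family_a", "family_b", "weight"])


@dataclass(frozen=True)
class CommunityPartition:
    membership: Mapping[str, int]
    quality_function: str
    resolution: float
    seed: int
    quality_score: float

    def frame(self) -> pd.DataFrame:
        rows = sorted(self.membership.items())
        return pd.DataFrame(rows, columns=["family_id", "community"])


def build_similarity_network(
    comparisons: Iterable[ProfileComparison],
    p_threshold: float = 0.05,
    combine: str = "max_weight",
    floor_zero_p: bool = True,
) -> SimilarityNetwork:
    """Combine reciprocal comparison records into one weighted edge per pair.

    ``combine='max_weight'`` keeps the best (minimum) p of the reciprocal
    records; ``'mean_weight'`` averages the −log10 p weights (geometric mean
    of p).  Pairs whose combined p exceeds ``p_threshold`` are dropped as
    edges; every family stays in the graph as a node regardless.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ValidationError("no comparison records supplied")
    if not 0.0 < p_threshold <= 1.0:
        raise ParameterError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if combine not in ("max_weight", "mean_weight"):
        raise ParameterError(f"combine must be 'max_weight' or 'mean_weight', got {combine!r}")

    graph = nx.Graph()
    pair_ps: dict[tuple[str, str], list[float]] = {}
    n_floored = 0
    for comp in comparisons:
        graph.add_node(comp.query_family)
        graph.add_node(comp.target_family)
        if comp.query_family == comp.target_family:
            continue  # self comparisons carry no relational information
        p = comp.p_value
        if p <= 0.0:
            if not floor_zero_p:
                raise ValidationError(
                    f"comparison {comp.query_family}->{comp.target_family}: "
                    "non-positive p_value with flooring disabled"
                )
            p = P_FLOOR
            n_floored += 1
        key = tuple(sorted((comp.query_family, comp.target_family)))
        pair_ps.setdefault(key, []).append(p)
    if n_floored:
        logger.warning("floored %d non-positive p-value(s) at %.0e", n_floored, P_FLOOR)

    for (a, b), ps in pair_ps.items():
        if combine == "max_weight":
            combined = min(ps)
        else:
            combined = 10.0 ** float(np.mean([math.log10(p) for p in ps]))
        if combined > p_threshold:
            continue
        graph.add_edge(a, b, weight=-math.log10(combined))
    return SimilarityNetwork(graph=graph)


def _to_igraph(net: SimilarityNetwork) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = []
    weights = []
    for a, b, data in net.graph.edges(data=True):
        edges.append((index[a], index[b]))
        weights.append(float(data["weight"]))
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def detect_communities(
    net: SimilarityNetwork,
    quality: str = "modularity",
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 20,
) -> CommunityPartition:
    """Leiden sub-network detection on the weighted similarity graph.

    Runs ``n_restarts`` independently seeded Leiden optimizations of the
    chosen quality function (modularity in its resolution-parametrized RB
    form, or CPM) and keeps the best partition by quality score.  Fully
    deterministic given (seed, n_restarts).
    """
    if len(net.graph) == 0:
        raise ValidationError("similarity network is empty")
    if resolution <= 0:
        raise ParameterError(f"resolution must be > 0, got {resolution}")
    if quality == "modularity":
        partition_type = leidenalg.RBConfigurationVertexPartition
    elif quality == "CPM":
        partition_type = leidenalg.CPMVertexPartition
    else:
        raise ParameterError(f"quality must be 'modularity' or 'CPM', got {quality!r}")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")

    g, nodes = _to_igraph(net)
    weights = g.es["weight"] if g.ecount() else None
    best = None
    best_quality = -math.inf
    for restart in range(n_restarts):
        part = leidenalg.find_partition(
            g, partition_type, weights=weights,
            resolution_parameter=resolution,
            seed=int(seed) + restart, n_iterations=-1,
        )
        q = part.quality()
        if q > best_quality:
            best_quality = q
            best = part
    membership = {node: int(best.membership[i]) for i, node in enumerate(nodes)}
    return CommunityPartition(
        membership=membership, quality_function=quality, resolution=resolution,
        seed=int(seed), quality_score=float(best_quality),
    )


def partition_agreement(partition: CommunityPartition,
                        reference: Mapping[str, int | str]) -> float:
    """Adjusted Rand index between a detected partition and reference labels."""
    nodes = sorted(partition.membership)
    if set(nodes) != set(reference):
        raise ValidationError("partition and reference cover different node sets")
    a = [partition.membership[n] for n in nodes]
    b = [reference[n] for n in nodes]
    return float(adjusted_rand_score(b, a))


def degree_attributes(net: SimilarityNetwork) -> dict[str, int]:
    """Node degree, the node-size attribute used in network exports."""
    return {n: int(d) for n, d in net.graph.degree()}
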