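"""Tissue network handling: seed-neighborhood extraction and topology stats.

The tissue network is an undirected graph whose edges carry a confidence
weight in [0, 1] (e.g. a functional-interaction posterior).  The
disease-specific subnetwork is the subgraph induced by a set of seed genes
plus their direct neighbors at or above a confidence cutoff.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class TissueNetwork:
    """Undirected weighted interaction graph; edge attribute ``confidence``."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "TissueNetwork":
        """Build a network, dropping self-loops and keeping the max
        confidence for duplicate edges (in either orientation)."""
        g = nx.Graph()
        n_loops = 0
        for a, b, conf in edges:
            conf = float(conf)
            if not 0.0 <= conf <= 1.0:
                raise ValueError(
                    f"edge ({a}, {b}) confidence {conf} outside [0, 1]"
                )
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        return cls(graph=g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Deterministic edge list: endpoints sorted within and across edges."""
        out = [tuple(sorted((a, b))) + (d["confidence"],)
               for a, b, d in self.graph.edges(data=True)]
        return sorted(out)


@dataclass
class Subnetwork:
    """Seed-anchored induced subgraph of a tissue network."""

    graph: nx.Graph
    seeds: frozenset[str]

    def __post_init__(self) -> None:
        if not self.seeds <= set(self.graph.nodes):
            raise ValueError("seeds must be a subset of subnetwork nodes")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class TopologyStats:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    avg_shortest_path: float
    diameter: int


def extract_subnetwork(network: TissueNetwork, seeds: Iterable[str],
                       cutoff: float = 0.1) -> Subnetwork:
    """Seeds plus their direct neighbors at confidence >= cutoff, with ALL
    qualifying edges among the selected nodes (induced subgraph).

    Seeds with no qualifying neighbor are kept as isolated nodes.  At least
    one seed must be present in the network.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    g = network.graph
    if not any(s in g for s in seeds):
        raise ValueError("no seed gene present in the network")
    nodes = set(seeds)
    for s in seeds:
        if s not in g:
            continue
        for v, d in g[s].items():
            if d["confidence"] >= cutoff:
                nodes.add(v)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes))  # sorted: deterministic edge orientation
    for a, b in itertools.combinations(sorted(nodes), 2):
        if g.has_edge(a, b) and g[a][b]["confidence"] >= cutoff:
            sub.add_edge(a, b, confidence=g[a][b]["confidence"])
    return Subnetwork(graph=sub, seeds=seeds)


def topology_stats(sub: Subnetwork) -> TopologyStats:
    """Summary topology of a subnetwork.

    Local clustering of nodes with degree < 2 counts as 0.  Average
    shortest path length and diameter are computed within the largest
    connected component (a single-node component yields 0 for both).
    """
    g = sub.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty subnetwork")
    e = g.number_of_edges()
    avg_degree = 2.0 * e / n
    avg_clustering = nx.average_clustering(g)  # degree<2 nodes contribute 0
    largest_cc = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    cc = g.subgraph(largest_cc)
    if cc.number_of_nodes() > 1:
        avg_sp = nx.average_shortest_path_length(cc)
        diam = nx.diameter(cc)
    else:
        avg_sp = 0.0
        diam = 0
    return TopologyStats(
        n_nodes=n,
        n_edges=e,
        avg_degree=avg_degree,
        avg_clustering=avg_clustering,
        avg_shortest_path=avg_sp,
        diameter=diam,
    )
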