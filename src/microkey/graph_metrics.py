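"""Global topology statistics and node centralities for interaction networks.

Global battery: node count N, edge count L, maximum possible edge count
L_max = N(N-1)/2, density C = L/L_max, diameter (longest finite shortest
path), average path length (mean over connected ordered pairs) and
transitivity (mean local clustering coefficient — for each node, the edge
density among its neighbors, 0 for degree < 2).

Local centralities: degree D (number of neighbors) and standardized
Freeman betweenness

    BC_i = [ sum over ordered pairs (j, k), j != i != k, of g_jk(i)/g_jk ]
           / ((N-1)(N-2)),

with g_jk the number of equally shortest j-k paths and g_jk(i) those
passing through i; the denominator is twice the number of node pairs
excluding i, so BC_i lies in [0, 1]. Pairs with no connecting path
contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .sparcc_network import InteractionNetwork

__all__ = ["GlobalStats", "CentralityScores", "degree", "betweenness", "global_stats"]


@dataclass
class GlobalStats:
    n_nodes: int
    n_edges: int
    l_max: int
    density: float
    diameter: int
    apl: float
    transitivity: float

    def as_row(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "density": self.density,
            "diameter": self.diameter,
            "APL": self.apl,
            "transitivity": self.transitivity,
        }


@dataclass
class CentralityScores:
    """Per-node centrality values in stable (insertion) node order."""

    metric: str
    scores: dict[str, float]

    @property
    def node_order(self) -> list[str]:
        return list(self.scores)

    def values(self) -> np.ndarray:
        return np.array(list(self.scores.values()), dtype=float)


def _graph(net: InteractionNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


def degree(net: InteractionNetwork | nx.Graph) -> CentralityScores:
    """Degree centrality: the number of directly linked partners."""
    g = _graph(net)
    return CentralityScores("degree", {n: float(d) for n, d in g.degree()})


def betweenness(net: InteractionNetwork | nx.Graph) -> CentralityScores:
    """Standardized Freeman node betweenness in [0, 1].

    Networks with fewer than 3 nodes have no intermediary positions; all
    scores are defined as 0.
    """
    g = _graph(net)
    if g.number_of_nodes() < 3:
        return CentralityScores("betweenness", {n: 0.0 for n in g.nodes})
    bc = nx.betweenness_centrality(g, normalized=True)
    return CentralityScores("betweenness", {n: float(bc[n]) for n in g.nodes})


def global_stats(net: InteractionNetwork | nx.Graph) -> GlobalStats:
    """The global topology battery for one network.

    Distances are unweighted hop counts. Disconnected pairs are excluded
    from the average path length and ignored for the diameter; for an
    edgeless network both are reported as 0.
    """
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global statistics need at least 2 nodes")
    L = g.number_of_edges()
    l_max = n * (n - 1) // 2
    density = L / l_max

    diameter = 0
    path_sum = 0
    path_count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                path_sum += d
                path_count += 1
                if d > diameter:
                    diameter = d
    apl = path_sum / path_count if path_count else 0.0
    transitivity = nx.average_clustering(g)  # deg<2 nodes contribute 0
    return GlobalStats(
        n_nodes=n,
        n_edges=L,
        l_max=l_max,
        density=density,
        diameter=diameter,
        apl=apl,
        transitivity=transitivity,
    )
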