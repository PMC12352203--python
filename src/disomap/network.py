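"""Summary statistics for a protein-protein interaction graph.

The graph is treated as simple and undirected after confidence
thresholding; edge weights are used only for filtering.  Clustering is
the unweighted Watts-Strogatz local coefficient, with nodes of degree
< 2 contributing 0 to the average (the STRING/NetworkX convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    avg_node_degree: float
    avg_local_clustering: float


def average_node_degree(n_nodes: int, n_edges: int) -> float:
    """2E/N, the mean degree of an undirected graph."""
    if n_nodes < 1:
        raise ValueError("graph must have at least one node")
    if n_edges < 0:
        raise ValueError("edge count must be non-negative")
    return 2.0 * n_edges / n_nodes


def average_local_clustering(graph: nx.Graph) -> float:
    """Mean local clustering coefficient over all nodes."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(graph.has_edge(v, v) for v in graph):
        raise ValueError("graph must be simple (no self-loops)")
    return float(nx.average_clustering(graph))


def summarize(graph: nx.Graph) -> GraphSummary:
    """Node/edge counts, average degree and average local clustering."""
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    return GraphSummary(n, m, average_node_degree(n, m),
                        average_local_clustering(graph))
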