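"""Percentile-thresholded disease–disease similarity networks.

Two diseases are connected when their phenotypic similarity falls in the
top fraction (default 0.5%) of the full distribution of similarity values.
The quantile is taken over every entry of the square similarity matrix —
including the diagonal self-similarities and both symmetric copies of each
off-diagonal value — matching a distribution of N² values for N diseases.
Self-loops are removed after thresholding, then nodes left with degree 0
are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "NetworkStats",
    "EmptyNetworkError",
    "similarity_threshold",
    "build_network",
    "network_stats",
    "write_graphml",
    "read_graphml",
    "write_edge_list_tsv",
    "write_stats_tsv",
]


class EmptyNetworkError(ValueError):
    """Raised when thresholding leaves no edges."""


@dataclass(frozen=True)
class NetworkStats:
    node_count: int
    edge_count: int
    average_degree: float  # 2 * edges / nodes
    component_count: int
    largest_component_size: int


def similarity_threshold(similarity: SimilarityMatrix, top_fraction: float) -> float:
    """The smallest value still inside the top ``top_fraction`` of all N² entries."""
    if not similarity.is_square:
        raise ValueError("network construction needs a square matrix")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    flat = similarity.values.ravel()
    m = max(1, math.ceil(top_fraction * flat.size))
    # m-th largest value; entries equal to it are kept, so the retained
    # fraction can slightly exceed top_fraction under ties
    return float(np.partition(flat, flat.size - m)[flat.size - m])


def build_network(
    similarity: SimilarityMatrix,
    top_fraction: float = 0.005,
    categories: Mapping[str, set[str]] | None = None,
) -> nx.Graph:
    """Threshold the similarity matrix into an undirected weighted network.

    Edges connect distinct diseases with similarity at or above the
    full-distribution quantile; each node carries a ``category`` attribute
    (sorted, comma-joined) when a category map is given.
    """
    threshold = similarity_threshold(similarity, top_fraction)
    ids = similarity.row_ids
    graph = nx.Graph()
    values = similarity.values
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(values[i, j])
            if w >= threshold:
                graph.add_edge(ids[i], ids[j], weight=w)
    # self-loops never enter; isolated nodes were never added
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no off-diagonal similarity reaches the threshold {threshold:.6g}"
        )
    if categories is not None:
        for node in graph.nodes:
            cats = sorted(categories.get(node, ()))
            graph.nodes[node]["category"] = ",".join(cats)
    return graph


def network_stats(network: nx.Graph) -> NetworkStats:
    """Node/edge counts, average degree and connected-component statistics."""
    n = network.number_of_nodes()
    if n == 0:
        raise EmptyNetworkError("network has no nodes")
    e = network.number_of_edges()
    components = list(nx.connected_components(network))
    return NetworkStats(
        node_count=n,
        edge_count=e,
        average_degree=2 * e / n,
        component_count=len(components),
        largest_component_size=max(len(c) for c in components),
    )


# ---------------------------------------------------------------------------
# I/O

def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list_tsv(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.10g}\n")


def write_stats_tsv(stats: NetworkStats, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"node_count\t{stats.node_count}\n")
        fh.write(f"edge_count\t{stats.edge_count}\n")
        fh.write(f"average_degree\t{stats.average_degree:.10g}\n")
        fh.write(f"component_count\t{stats.component_count}\n")
        fh.write(f"largest_component_size\t{stats.largest_component_size}\n")
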