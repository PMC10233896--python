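"""Graph-topology metrics of the inferred functional network.

Measures follow the standard brain-connectivity conventions: average
connectivity (mean degree over connected neurons), mean Euclidean distance
between connected neurons, global efficiency (mean inverse directed
shortest-path length), local efficiency (mean global efficiency of each
node's neighbourhood subgraph), and Newman modularity Q of a Louvain
partition. Efficiencies are computed on the directed graph the significance
rule produces; modularity is computed after OR-symmetrization, matching the
undirected tradition of the toolbox family these measures come from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

__all__ = [
    "TopologyMetrics",
    "average_connectivity",
    "mean_connection_distance",
    "global_efficiency",
    "local_efficiency",
    "modularity_partition",
    "summarize_topology",
]


@dataclass
class TopologyMetrics:
    """One recording's network-organization summary (JSON-serializable)."""

    avg_connectivity: float
    mean_connection_distance_um: float | None
    g_eff: float
    l_eff: float
    modularity_q: float
    n_modules: int
    neurons_per_module: list[int]
    partition: list[int]

    def to_dict(self) -> dict:
        return asdict(self)


def _check_square(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return (a != 0).astype(np.uint8)


def average_connectivity(adjacency: np.ndarray) -> float:
    """Mean number of connections (in + out) per connected neuron.

    Neurons without any connection are excluded from the average; an empty
    graph returns 0.
    """
    a = _check_square(adjacency)
    degree = a.sum(axis=0) + a.sum(axis=1)
    connected = degree > 0
    if not connected.any():
        return 0.0
    return float(degree[connected].mean())


def mean_connection_distance(
    adjacency: np.ndarray, positions: np.ndarray
) -> float | None:
    """Mean Euclidean distance (µm) between connected neurons; None if no edges."""
    a = _check_square(adjacency)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != a.shape[0]:
        raise ValueError("positions must cover every node")
    src, dst = np.nonzero(a)
    if src.size == 0:
        return None
    d = np.linalg.norm(positions[src] - positions[dst], axis=1)
    return float(d.mean())


def _pairwise_inverse_distance_sum(g: nx.DiGraph) -> float:
    total = 0.0
    for _node, dists in nx.all_pairs_shortest_path_length(g):
        for other, d in dists.items():
            if other != _node and d > 0:
                total += 1.0 / d
    return total


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs, directed shortest paths.

    Unreachable pairs contribute 0; ranges from 0 (no communication) to 1
    (complete graph).
    """
    a = _check_square(adjacency)
    n = a.shape[0]
    if n < 2:
        return 0.0
    g = nx.from_numpy_array(a, create_using=nx.DiGraph)
    return _pairwise_inverse_distance_sum(g) / (n * (n - 1))


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbourhood subgraph.

    A node's neighbourhood is the union of its in- and out-neighbours
    (excluding the node); nodes with fewer than two neighbours contribute 0.
    """
    a = _check_square(adjacency)
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(a[v] | a[:, v])
        nbrs = nbrs[nbrs != v]
        if nbrs.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def modularity_partition(
    adjacency: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float, int, list[int]]:
    """Louvain community detection on the OR-symmetrized graph.

    Returns ``(partition, Q, n_modules, neurons_per_module)`` with Newman
    modularity Q of the returned partition. An edgeless graph returns a
    single module with Q = 0. Deterministic given the seed.
    """
    a = _check_square(adjacency)
    n = a.shape[0]
    sym = ((a | a.T) != 0).astype(np.uint8)
    np.fill_diagonal(sym, 0)
    if sym.sum() == 0:
        return np.zeros(n, dtype=int), 0.0, 1, [n]
    g = nx.from_numpy_array(sym)
    communities = nx.community.louvain_communities(g, seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    partition = np.zeros(n, dtype=int)
    for m, comm in enumerate(communities):
        for v in comm:
            partition[v] = m
    q = nx.community.modularity(g, communities)
    sizes = [len(c) for c in communities]
    return partition, float(q), len(communities), sizes


def summarize_topology(
    adjacency: np.ndarray,
    positions: np.ndarray | None = None,
    seed: int = 0,
) -> TopologyMetrics:
    """All topology measures of one adjacency matrix in a single record."""
    a = _check_square(adjacency)
    if positions is not None:
        dist = mean_connection_distance(a, positions)
    else:
        dist = None
    partition, q, n_modules, sizes = modularity_partition(a, seed=seed)
    return TopologyMetrics(
        avg_connectivity=average_connectivity(a),
        mean_connection_distance_um=dist,
        g_eff=global_efficiency(a),
        l_eff=local_efficiency(a),
        modularity_q=q,
        n_modules=n_modules,
        neurons_per_module=sizes,
        partition=[int(p) for p in partition],
    )
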