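"""Graph metrics for binary undirected networks.

Global measures: clustering coefficient (segregation), characteristic path
length (integration), and small-worldness (their balance, benchmarked
against null networks).  Nodal measures: degree and betweenness centrality.

Conventions match the binary-network toolboxes common in connectomics:
a node with degree < 2 has clustering 0 and the network clustering is the
unweighted mean over ALL nodes; path length averages hop counts over
reachable ordered pairs only, with unreachable pairs counted separately;
betweenness is reported unnormalized (any group-mean normalization happens
at comparison time, where it cancels constant factors).
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .construction import BinaryGraph
from .exceptions import DegenerateDataError


@dataclass
class GlobalMetrics:
    clustering_coefficient: float
    path_length: float
    n_unreachable_pairs: int
    density: float


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    region_names: list


# ----------------------------------------------------------------------

def clustering_coefficient(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = 2 t_i / (k_i (k_i - 1)) and the network mean.

    t_i counts triangles through node i; C_i = 0 where k_i < 2.  The
    network value is the unweighted mean over all nodes.
    """
    a = graph.adjacency.astype(float)
    per_node = _clustering_rows(a[None, :, :])[0]
    return per_node, float(per_node.mean())


def _clustering_rows(stack: np.ndarray) -> np.ndarray:
    """Batched per-node clustering for a (D, N, N) adjacency stack."""
    a = stack.astype(float)
    k = a.sum(axis=2)
    # ((A @ A) * A).sum over j equals 2 * (#triangles through i)
    two_t = (np.matmul(a, a) * a).sum(axis=2)
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, two_t / denom, 0.0)
    return c


def clustering_mean_curve(stack: np.ndarray) -> np.ndarray:
    """Network-mean clustering for each adjacency in a (D, N, N) stack."""
    return _clustering_rows(stack).mean(axis=1)


def characteristic_path_length(graph: BinaryGraph) -> tuple[float, int]:
    """Mean hop count over reachable ordered pairs, plus unreachable count."""
    return path_length_from_adjacency(graph.adjacency)


def path_length_from_adjacency(adj: np.ndarray) -> tuple[float, int]:
    adj = np.asarray(adj)
    n = adj.shape[0]
    if adj.sum() == 0:
        raise DegenerateDataError("path length undefined: graph has no edges")
    dist = shortest_path(csr_matrix(adj), method="D", directed=False,
                         unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_unreachable = int((off & ~finite).sum())
    return float(dist[finite].mean()), n_unreachable


def nodal_degree(graph: BinaryGraph) -> np.ndarray:
    return graph.adjacency.sum(axis=1).astype(int)


def betweenness_centrality(graph: BinaryGraph) -> np.ndarray:
    """Unnormalized betweenness b_i = sum over pairs s<t of sigma_st(i)/sigma_st
    (Brandes accumulation)."""
    return betweenness_from_adjacency(graph.adjacency)


def betweenness_from_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    edges = np.argwhere(np.triu(adj, 1))
    g = ig.Graph(n=adj.shape[0], edges=[tuple(e) for e in edges])
    return np.asarray(g.betweenness(directed=False), dtype=float)


def small_worldness(c_obs: float, l_obs: float, c_null: float,
                    l_null: float) -> tuple[float, float, float]:
    """gamma = C/C_null, lambda = L/L_null, sigma = gamma/lambda."""
    for name, v in (("c_obs", c_obs), ("l_obs", l_obs),
                    ("c_null", c_null), ("l_null", l_null)):
        if not np.isfinite(v) or v <= 0:
            raise DegenerateDataError(
                f"small-worldness undefined: {name} = {v} (degenerate null ensemble?)")
    gamma = c_obs / c_null
    lam = l_obs / l_null
    return gamma, lam, gamma / lam


def global_metrics(graph: BinaryGraph) -> GlobalMetrics:
    _, c_mean = clustering_coefficient(graph)
    l_p, unreachable = characteristic_path_length(graph)
    return GlobalMetrics(clustering_coefficient=c_mean, path_length=l_p,
                         n_unreachable_pairs=unreachable, density=graph.density)


def nodal_metrics(graph: BinaryGraph) -> NodalMetrics:
    names = graph.region_names or [f"N{i}" for i in range(graph.n_nodes)]
    return NodalMetrics(degree=nodal_degree(graph),
                        betweenness=betweenness_centrality(graph),
                        region_names=list(names))
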