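"""Ten per-drug network features of the projected drug graph.

Column letters follow the field's shorthand: D degree centrality, W weighted
degree (strength), E eigenvector centrality, O closeness, C clustering
coefficient, B betweenness, A authority, H hub, T triangles, P weighted
PageRank.  Exactly two measures — W and P — consume the normalised edge
weights; the other eight operate on edge existence alone, so permuting the
weights while keeping the topology fixed can only move the W and P columns.

Conventions: degree is divided by N−1; closeness uses unweighted shortest
paths with Wasserman–Faust scaling on disconnected graphs; betweenness is
Brandes' accumulation normalised by 2/((N−1)(N−2)); eigenvector and HITS
vectors are non-negative with unit Euclidean norm; PageRank sums to one.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .network_build import WeightedDrugGraph

__all__ = [
    "ConvergenceError",
    "NETWORK_FEATURE_COLUMNS",
    "LETTER_TO_COLUMN",
    "degree_centrality",
    "weighted_degree",
    "eigenvector_centrality",
    "closeness_centrality",
    "clustering_coefficient",
    "betweenness_centrality",
    "hits_scores",
    "triangle_counts",
    "weighted_pagerank",
    "all_features",
]

#: fixed column order of the feature table (letters D W E O C B A H T P)
NETWORK_FEATURE_COLUMNS = (
    "degree",
    "weighted_degree",
    "eigenvector",
    "closeness",
    "clustering",
    "betweenness",
    "authority",
    "hub",
    "triangles",
    "pagerank",
)

LETTER_TO_COLUMN = {
    "D": "degree",
    "W": "weighted_degree",
    "E": "eigenvector",
    "O": "closeness",
    "C": "clustering",
    "B": "betweenness",
    "A": "authority",
    "H": "hub",
    "T": "triangles",
    "P": "pagerank",
}


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""

    def __init__(self, what: str, iterations: int):
        super().__init__(f"{what} did not converge within {iterations} iterations")
        self.iterations = iterations


def _largest_component_mask(graph: WeightedDrugGraph) -> np.ndarray:
    n_comp, labels = connected_components(graph.sparse_adjacency(), directed=False)
    if n_comp == 1:
        return np.ones(graph.n_nodes, dtype=bool)
    warnings.warn(
        "graph is disconnected; spectral scores computed on the largest "
        "component, zero elsewhere",
        stacklevel=3,
    )
    sizes = np.bincount(labels)
    return labels == sizes.argmax()


def degree_centrality(graph: WeightedDrugGraph) -> np.ndarray:
    """deg(v)/(N−1) on the binary graph."""
    if graph.n_nodes < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return graph.degrees() / (graph.n_nodes - 1)


def weighted_degree(graph: WeightedDrugGraph) -> np.ndarray:
    """Node strength: sum of normalised incident edge weights."""
    return graph.strengths()


def eigenvector_centrality(
    graph: WeightedDrugGraph, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Principal eigenvector of the binary adjacency by power iteration,
    non-negative and normalised to unit Euclidean norm.

    Iterates (A + I)x, which has the same principal eigenvector as A but
    avoids the sign oscillation of plain power iteration on bipartite
    graphs, whose extreme eigenvalues tie in magnitude."""
    mask = _largest_component_mask(graph)
    a = graph.adjacency()[np.ix_(mask, mask)]
    k = a.shape[0]
    x = np.full(k, 1.0 / np.sqrt(k))
    for _ in range(max_iter):
        x_new = a @ x + x
        nrm = np.linalg.norm(x_new)
        if nrm == 0:  # no edges in the component
            x_new = x
        else:
            x_new = x_new / nrm
        if np.max(np.abs(x_new - x)) < tol:
            out = np.zeros(graph.n_nodes)
            out[mask] = np.abs(x_new)
            return out
        x = x_new
    raise ConvergenceError("eigenvector centrality", max_iter)


def closeness_centrality(graph: WeightedDrugGraph) -> np.ndarray:
    """(N−1)/Σ_u dist(v,u) on unweighted shortest paths.

    On a disconnected graph each node's score is computed within its
    component and scaled by (reachable−1)/(N−1) (Wasserman–Faust), which
    reduces to the plain formula when the graph is connected.
    """
    n = graph.n_nodes
    dist = shortest_path(graph.sparse_adjacency(), method="D", unweighted=True)
    out = np.zeros(n)
    for v in range(n):
        finite = np.isfinite(dist[v])
        r = int(finite.sum())  # reachable incl. self
        total = dist[v, finite].sum()
        if r > 1 and total > 0:
            out[v] = ((r - 1) / total) * ((r - 1) / (n - 1)) if n > 1 else 0.0
    return out


def clustering_coefficient(graph: WeightedDrugGraph) -> np.ndarray:
    """Fraction of a node's neighbour pairs that are connected; 0 when
    degree < 2."""
    a = graph.adjacency()
    deg = graph.degrees().astype(float)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    return np.divide(2.0 * tri, denom, out=np.zeros(graph.n_nodes), where=denom > 0)


def betweenness_centrality(graph: WeightedDrugGraph) -> np.ndarray:
    """Brandes' algorithm on the binary graph, endpoints excluded,
    normalised by 2/((N−1)(N−2))."""
    n = graph.n_nodes
    if n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for u, v in graph.edges:
        nbrs[u].append(int(v))
        nbrs[v].append(int(u))

    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair counted twice (once per endpoint as source)
    bc /= 2.0
    return bc * (2.0 / ((n - 1) * (n - 2)))


def hits_scores(
    graph: WeightedDrugGraph, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """HITS hub and authority scores with each undirected edge treated as a
    reciprocal directed pair; returns (hub, authority), each L2-normalised.

    One iteration applies a full HITS round, a <- A'h then h <- Aa with L2
    normalisation, i.e. power iteration with A'A = A^2 from a uniform
    start.  Because the adjacency is symmetric, AA' = A'A and the hub and
    authority fixed points coincide; this is asserted before returning.
    (Updating hub and authority on alternating half-steps instead would
    leave them on different odd/even-power limits on bipartite graphs,
    where the top eigenvalue of A^2 is degenerate.)
    """
    mask = _largest_component_mask(graph)
    a = graph.adjacency()[np.ix_(mask, mask)]
    k = a.shape[0]
    h = np.full(k, 1.0 / np.sqrt(k))
    for _ in range(max_iter):
        auth_new = a.T @ h
        nrm = np.linalg.norm(auth_new)
        auth_new = auth_new / nrm if nrm else h
        h_new = a @ auth_new
        nrm = np.linalg.norm(h_new)
        h_new = h_new / nrm if nrm else auth_new
        if np.max(np.abs(h_new - h)) < tol:
            # hub iterates AA', authority iterates A'A; for the symmetric
            # adjacency these matrices are equal, so the limits coincide
            h = np.abs(h_new)
            auth = h.copy()
            assert np.max(np.abs(h - auth)) < 1e-6, "hub != authority on undirected graph"
            hub_full = np.zeros(graph.n_nodes)
            auth_full = np.zeros(graph.n_nodes)
            hub_full[mask] = h
            auth_full[mask] = auth
            return hub_full, auth_full
        h = h_new
    raise ConvergenceError("HITS", max_iter)


def triangle_counts(graph: WeightedDrugGraph) -> np.ndarray:
    """Number of triangles through each node on the binary graph."""
    a = graph.adjacency()
    return np.rint(np.diag(a @ a @ a) / 2.0).astype(int)


def weighted_pagerank(
    graph: WeightedDrugGraph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Weighted PageRank with undirected edges treated as bidirectional.

    PR(v) = (1−d)/N + d · Σ_{u∈nbr(v)} PR(u)·w(u,v)/strength(u); nodes with
    zero strength redistribute their mass uniformly.  The result sums to 1.
    """
    n = graph.n_nodes
    w = graph.adjacency(weight="norm")
    strength = w.sum(axis=1)
    dangling = strength <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        trans = np.where(dangling[:, None], 0.0, w / np.where(strength == 0, 1.0, strength)[:, None])
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = (1.0 - damping) / n + damping * (trans.T @ x + x[dangling].sum() / n)
        if np.abs(x_new - x).sum() < tol:
            return x_new / x_new.sum()
        x = x_new
    raise ConvergenceError("weighted PageRank", max_iter)


def all_features(graph: WeightedDrugGraph) -> pd.DataFrame:
    """Assemble the ten features into a drugs × 10 table in the fixed
    column order D, W, E, O, C, B, A, H, T, P."""
    hub, authority = hits_scores(graph)
    data = {
        "degree": degree_centrality(graph),
        "weighted_degree": weighted_degree(graph),
        "eigenvector": eigenvector_centrality(graph),
        "closeness": closeness_centrality(graph),
        "clustering": clustering_coefficient(graph),
        "betweenness": betweenness_centrality(graph),
        "authority": authority,
        "hub": hub,
        "triangles": triangle_counts(graph),
        "pagerank": weighted_pagerank(graph),
    }
    return pd.DataFrame(data, index=graph.node_ids, columns=list(NETWORK_FEATURE_COLUMNS))
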