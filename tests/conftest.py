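import numpy as np
import pytest

from adrnet import IncidenceMatrix, WeightedDrugGraph, normalize_weights, project_bipartite


@pytest.fixture
def worked_incidence() -> IncidenceMatrix:
    """The 4-drug / 4-ADR toy instance: d1={a1}, d2={a1,a2}, d3={a1,a3,a4},
    d4={a2,a3,a4}."""
    values = np.array(
        [
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [1, 0, 1, 1],
            [0, 1, 1, 1],
        ]
    )
    return IncidenceMatrix(["d1", "d2", "d3", "d4"], ["a1", "a2", "a3", "a4"], values)


@pytest.fixture
def worked_graph(worked_incidence) -> WeightedDrugGraph:
    return normalize_weights(project_bipartite(worked_incidence))


def graph_from_edges(n: int, edge_weight_pairs) -> WeightedDrugGraph:
    """Build a WeightedDrugGraph from (u, v, norm_weight) triples on nodes
    0..n-1; raw weights are set to 1 (unused by topology-only measures)."""
    edges, weights = [], []
    for u, v, w in edge_weight_pairs:
        u, v = (u, v) if u < v else (v, u)
        edges.append((u, v))
        weights.append(w)
    edges = np.array(edges, dtype=int).reshape(-1, 2)
    order = np.lexsort((edges[:, 1], edges[:, 0])) if len(edges) else []
    return WeightedDrugGraph(
        [f"n{i}" for i in range(n)],
        edges[order],
        np.ones(len(edges), dtype=int),
        np.asarray(weights, dtype=float)[order],
    )


def graph_from_networkx(g, rng=None) -> WeightedDrugGraph:
    """Convert a networkx graph; uses edge attribute 'weight' as the
    normalised weight when present, else draws uniform weights in (0.1, 1)."""
    nodes = sorted(g.nodes())
    index = {node: i for i, node in enumerate(nodes)}
    triples = []
    for u, v, data in g.edges(data=True):
        w = data.get("weight")
        if w is None:
            w = 0.1 + 0.9 * rng.random() if rng is not None else 1.0
            g[u][v]["weight"] = w
        triples.append((index[u], index[v], float(w)))
    return graph_from_edges(len(nodes), triples)


def random_connected_graph(nx, n: int, p: float, seed: int, rng):
    """Connected Erdős–Rényi graph with uniform edge weights attached."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    attempt = 0
    while not nx.is_connected(g) or g.number_of_edges() < 2:
        attempt += 1
        g = nx.gnp_random_graph(n, p, seed=seed + 10_000 * attempt)
    wg = graph_from_networkx(g, rng)
    return g, wg
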