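"""Drug-to-drug network construction from a drug–ADR incidence matrix.

The bipartite drug–ADR graph is projected onto drugs: two drugs are joined
iff they share at least one ADR, and the raw edge weight is the number of
shared ADRs (the dot product of the two incidence rows).  Raw weights are
then min–max normalised to [0, 1] so that network features remain on a
scale comparable with the other drug features.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .dataset_io import IncidenceMatrix

__all__ = [
    "WeightedDrugGraph",
    "NetworkSummary",
    "project_bipartite",
    "normalize_weights",
    "summarize",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class WeightedDrugGraph:
    """Undirected drug graph with shared-ADR edge weights.

    Edges are stored once per unordered pair as index pairs ``(u, v)`` with
    ``u < v`` into ``node_ids``.  ``raw_weight`` is the shared-ADR count
    (>= 1 for every stored edge); ``norm_weight`` is filled by
    :func:`normalize_weights` and lies in [0, 1].
    """

    node_ids: list[str]
    edges: np.ndarray  # (m, 2) int
    raw_weight: np.ndarray  # (m,) int
    norm_weight: np.ndarray | None = None
    #: optional per-edge list of shared ADR ids (debug only)
    shared_adrs: list[list[str]] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.raw_weight)

    def adjacency(self, weight: str | None = None) -> np.ndarray:
        """Dense symmetric adjacency; ``weight`` is None (binary), ``"raw"``
        or ``"norm"``."""
        n = self.n_nodes
        a = np.zeros((n, n), dtype=float)
        if self.n_edges:
            if weight is None:
                w = np.ones(self.n_edges)
            elif weight == "raw":
                w = self.raw_weight.astype(float)
            elif weight == "norm":
                if self.norm_weight is None:
                    raise ValueError("norm_weight not set; call normalize_weights first")
                w = self.norm_weight
            else:
                raise ValueError(f"unknown weight kind {weight!r}")
            u, v = self.edges[:, 0], self.edges[:, 1]
            a[u, v] = w
            a[v, u] = w
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def strengths(self) -> np.ndarray:
        """Sum of normalised incident edge weights per node."""
        if self.norm_weight is None:
            raise ValueError("norm_weight not set; call normalize_weights first")
        s = np.zeros(self.n_nodes, dtype=float)
        if self.n_edges:
            np.add.at(s, self.edges[:, 0], self.norm_weight)
            np.add.at(s, self.edges[:, 1], self.norm_weight)
        return s

    def sparse_adjacency(self, weight: str | None = None):
        n = self.n_nodes
        if not self.n_edges:
            return coo_matrix((n, n)).tocsr()
        if weight is None:
            w = np.ones(self.n_edges)
        elif weight == "raw":
            w = self.raw_weight.astype(float)
        else:
            w = self.norm_weight
        u, v = self.edges[:, 0], self.edges[:, 1]
        return coo_matrix(
            (np.r_[w, w], (np.r_[u, v], np.r_[v, u])), shape=(n, n)
        ).tocsr()


@dataclass
class NetworkSummary:
    """Global statistics of the projected drug graph."""

    node_count: int
    edge_count: int
    average_degree: float
    diameter: int
    average_path_length: float
    density: float
    average_clustering: float
    #: True when the graph is disconnected and path statistics were
    #: computed on the largest connected component only.
    path_stats_on_largest_component: bool = False


def project_bipartite(incidence: IncidenceMatrix, keep_shared: bool = False) -> WeightedDrugGraph:
    """Project the drug–ADR bipartite graph onto drugs.

    An edge {u, v} exists iff drugs u and v share at least one ADR; its raw
    weight is the size of the shared-ADR set, i.e. the dot product of the
    two binary incidence rows.  Pairs sharing nothing get no edge.
    """
    values = incidence.values.astype(np.int64)
    shared = values @ values.T
    iu, iv = np.triu_indices(incidence.n_drugs, k=1)
    w = shared[iu, iv]
    keep = w > 0
    edges = np.column_stack([iu[keep], iv[keep]]).astype(np.int64)
    raw = w[keep]
    shared_lists = None
    if keep_shared:
        adr_ids = np.asarray(incidence.adr_ids)
        shared_lists = [
            list(adr_ids[(values[u] & values[v]).astype(bool)]) for u, v in edges
        ]
    return WeightedDrugGraph(list(incidence.drug_ids), edges, raw, None, shared_lists)


def normalize_weights(graph: WeightedDrugGraph) -> WeightedDrugGraph:
    """Min–max normalise raw weights: x -> (x - min) / (max - min).

    The smallest raw weight maps to 0 and the largest to 1.  When all raw
    weights are equal the formula is undefined; every edge is then given
    norm weight 1 so that edge existence is preserved.
    """
    if graph.n_edges == 0:
        raise ValueError("cannot normalise an edgeless graph")
    raw = graph.raw_weight.astype(float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        norm = np.ones_like(raw)
    else:
        norm = (raw - lo) / (hi - lo)
    return replace(graph, norm_weight=norm)


def summarize(graph: WeightedDrugGraph) -> NetworkSummary:
    """Node/edge counts, mean degree 2E/N, density, unweighted diameter and
    average shortest-path length, and mean local clustering coefficient.

    Path statistics are computed over all ordered reachable pairs; on a
    disconnected graph they are computed on the largest connected component
    and flagged.  Nodes of degree < 2 contribute 0 to the mean clustering.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("cannot summarise an empty graph")
    m = graph.n_edges
    average_degree = 2.0 * m / n
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))

    adj = graph.sparse_adjacency()
    n_comp, labels = connected_components(adj, directed=False)
    flagged = n_comp > 1
    if flagged:
        sizes = np.bincount(labels)
        nodes = np.flatnonzero(labels == sizes.argmax())
    else:
        nodes = np.arange(n)

    if len(nodes) < 2:
        diameter, apl = 0, 0.0
    else:
        dist = shortest_path(adj[np.ix_(nodes, nodes)], method="D", unweighted=True)
        off = ~np.eye(len(nodes), dtype=bool)
        diameter = int(dist[off].max())
        apl = float(dist[off].mean())

    a = graph.adjacency()
    deg = graph.degrees().astype(float)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    local = np.divide(2.0 * tri, denom, out=np.zeros(n), where=denom > 0)

    return NetworkSummary(
        node_count=n,
        edge_count=m,
        average_degree=average_degree,
        diameter=diameter,
        average_path_length=apl,
        density=density,
        average_clustering=float(local.mean()),
        path_stats_on_largest_component=flagged,
    )


def write_edge_list(graph: WeightedDrugGraph, path) -> None:
    """TSV export: drug_a, drug_b, raw_weight, norm_weight."""
    with open(path, "w") as fh:
        fh.write("drug_a\tdrug_b\traw_weight\tnorm_weight\n")
        norm = graph.norm_weight
        for k, (u, v) in enumerate(graph.edges):
            nw = "" if norm is None else repr(float(norm[k]))
            fh.write(
                f"{graph.node_ids[u]}\t{graph.node_ids[v]}\t{int(graph.raw_weight[k])}\t{nw}\n"
            )


def write_graphml(graph: WeightedDrugGraph, path) -> None:
    """Minimal GraphML export for interoperability with graph viewers."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    root = ET.Element("graphml", xmlns=ns)
    for key_id, name in (("d0", "raw_weight"), ("d1", "norm_weight")):
        ET.SubElement(
            root, "key", id=key_id, **{"for": "edge", "attr.name": name, "attr.type": "double"}
        )
    g = ET.SubElement(root, "graph", id="drugs", edgedefault="undirected")
    for node in graph.node_ids:
        ET.SubElement(g, "node", id=node)
    for k, (u, v) in enumerate(graph.edges):
        e = ET.SubElement(g, "edge", source=graph.node_ids[u], target=graph.node_ids[v])
        d0 = ET.SubElement(e, "data", key="d0")
        d0.text = str(int(graph.raw_weight[k]))
        if graph.norm_weight is not None:
            d1 = ET.SubElement(e, "data", key="d1")
            d1.text = repr(float(graph.norm_weight[k]))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
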