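"""Project a drug–ADR incidence matrix onto a weighted drug-to-drug network.

Two drugs are connected when they share at least one ADR; the edge weight
counts shared ADRs and is then min–max normalised to [0, 1].  The tiny
4-drug instance below shows the construction by hand; the summary of a
simulated 200-drug network shows the near-complete topology this projection
produces, where the weights — not the edges — carry the information.
"""

import numpy as np

from adrnet import (
    IncidenceMatrix,
    SimulationConfig,
    normalize_weights,
    project_bipartite,
    simulate_dataset,
    summarize,
)

# d1 causes a1; d2 causes a1,a2; d3 causes a1,a3,a4; d4 causes a2,a3,a4
toy = IncidenceMatrix(
    ["d1", "d2", "d3", "d4"],
    ["a1", "a2", "a3", "a4"],
    np.array([[1, 0, 0, 0], [1, 1, 0, 0], [1, 0, 1, 1], [0, 1, 1, 1]]),
)
graph = normalize_weights(project_bipartite(toy))
print("toy projection edges (raw = shared ADRs, norm = min-max scaled):")
for (u, v), raw, norm in zip(graph.edges, graph.raw_weight, graph.norm_weight):
    print(f"  {graph.node_ids[u]}–{graph.node_ids[v]}: raw={raw} norm={norm}")
print("Only d3–d4 share two ADRs, so it is the single maximum-weight edge.\n")

dataset = simulate_dataset(SimulationConfig(seed=0))
summary = summarize(normalize_weights(project_bipartite(dataset.incidence)))
print("simulated 200-drug network summary:")
print(f"  nodes {summary.node_count}, edges {summary.edge_count}")
print(f"  density {summary.density:.3f}, average degree {summary.average_degree:.1f}")
print(f"  diameter {summary.diameter}, average path length {summary.average_path_length:.3f}")
print(f"  average clustering {summary.average_clustering:.3f}")
print("Shared-ADR projections are nearly complete graphs: almost every "
      "drug pair shares some ADR, so edge existence alone says little and "
      "the normalised weights do the discriminating.")
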