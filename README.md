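# adrnet

Drug-to-drug network features for adverse drug reaction (ADR) prediction.

## The problem

Post-marketing pharmacovigilance compendia record which drugs are associated
with which ADRs, plus one-hot drug descriptors (chemical substructures,
enzymes, indications, pathways, targets, transporters). Predicting a drug's
unknown ADRs from these descriptors alone works poorly: the per-ADR labels
are severely imbalanced and the descriptors are high-dimensional and sparse.
`adrnet` implements a network-based alternative: drugs that share ADRs are
likely to act on the same proteins through the same pathways, so their
*position* in a shared-ADR network is itself predictive.

The pipeline:

1. **Projection.** The bipartite drug–ADR graph is projected onto drugs.
   Edge weight = number of shared ADRs (the dot product of the two binary
   incidence rows), then min–max normalised:
   `w_new = (w − w_min) / (w_max − w_min)`.
2. **Network features.** Ten per-drug centrality measures, letter-coded
   D, W, E, O, C, B, A, H, T, P: degree centrality `deg(v)/(N−1)`, weighted
   degree (strength) `s(v) = Σ_u w(u,v)`, eigenvector centrality, closeness,
   local clustering coefficient, betweenness (Brandes), HITS authority and
   hub, triangle count, and weighted PageRank
   `PR(v) = (1−d)/N + d Σ_u PR(u) w(u,v)/s(u)` with damping `d = 0.85`.
   Exactly W and P consume the edge weights; the other eight see topology
   only.
3. **Learning features.** The one-hot drug descriptors are reduced by PCA
   to 10 components and the network features are appended cumulatively
   (baseline, +D, +DW, … , +all ten — the "feature ladder").
4. **Evaluation.** For every ADR with ≥ 15 associated drugs, seven
   classifiers (LR, DT, XGB, RF, SVM, kNN, ANN) are scored by 10-fold
   cross-validated AUROC (Mann–Whitney rank statistic, ties = 0.5).
   Training folds whose positive/negative ratio is below 0.4 are rebalanced
   with SMOTE (k = 5 neighbours, target minority count
   `floor(0.43 × majority)`); test folds are never touched.
5. **Importance.** Per ADR, Wald p-values of an unpenalised logistic
   regression on the 20-feature set are aggregated per network feature.

Real compendia of this kind are not freely redistributable, so the package
ships a first-class synthetic generator (`adrnet.synthetic_data`): latent
"mechanisms" with Zipf-distributed popularity govern random subsets of ADRs
and feature columns, reproducing the heavy-tailed ADR frequency profile and
the coupling between shared ADRs and shared features that the method
exploits.

## Worked example

```python
import numpy as np
from adrnet import IncidenceMatrix, project_bipartite, normalize_weights

inc = IncidenceMatrix(
    ["d1", "d2", "d3", "d4"],
    ["a1", "a2", "a3", "a4"],
    np.array([[1,0,0,0], [1,1,0,0], [1,0,1,1], [0,1,1,1]]),
)
g = normalize_weights(project_bipartite(inc))
for (u, v), raw, norm in zip(g.edges, g.raw_weight, g.norm_weight):
    print(g.node_ids[u], g.node_ids[v], raw, norm)
```

prints the five edges of the projected graph:

```
d1 d2 1 0.0
d1 d3 1 0.0
d2 d3 1 0.0
d2 d4 1 0.0
d3 d4 2 1.0
```

Drugs 3 and 4 share two ADRs while every other connected pair shares one,
so d3–d4 is the unique maximum-weight edge; after min–max normalisation it
carries weight 1 and all others 0.

The scripts in `examples/` walk through each stage on simulated data. The
end-to-end run (`examples/05_evaluate_ladder.py`, ~1 minute) generates 200
drugs × 150 ADRs with *pure-noise* drug features and prints:

```
mean AUROC across eligible ADRs (logistic regression):
            baseline  baseline+DW  baseline+DWEOCBAHTP
LR             0.509        0.682                0.694

paired AUROC gain over 32 ADRs: 0.185 ± 0.024 (z = 7.6)
```

The baseline sits at chance because the drug features are noise by
construction; the ~0.19 AUROC lift is contributed entirely by the network
features, and the weighted degree / weighted PageRank columns receive the
smallest mean logistic-regression p-values (0.095 and 0.096) of the ten —
the edge weights, not mere edge existence, carry the signal.

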