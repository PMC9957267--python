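# Methods

## Model

`adrnet` treats ADR prediction as a per-label binary classification problem
over drugs, with one feature vector per drug shared across all labels. The
central modelling idea is that a drug's *position in the shared-ADR
network* summarises latent pharmacology: two drugs that provoke the same
reactions plausibly engage the same targets and pathways, so network
centrality — especially weight-aware centrality — is informative about any
individual reaction.

The network is the one-mode projection of the bipartite drug–ADR graph onto
drugs. For drugs `u, v` with binary incidence rows `x_u, x_v`, the raw edge
weight is `x_u · x_v` (shared-ADR count); pairs sharing nothing get no
edge. Raw weights are min–max normalised to `[0, 1]`. When all raw weights
are equal the normalisation formula is undefined (`w_max = w_min`); we
define every normalised weight as 1, preserving edge existence rather than
annihilating the network. Shared-ADR projections of realistic incidence
matrices are nearly complete (density ≈ 0.96 on the simulated default), so
the information sits almost entirely in the weights.

An important property of this design, preserved deliberately: the network
is built once from the *full* incidence matrix, so the target ADR's own
associations contribute to the edge weights used to predict it. This is
inherent to the original procedure and is the main reason weight-aware
features predict so well. `PipelineConfig(holdout_adr_edges=True)` rebuilds
the network without the target ADR's column for a leakage-free variant.
Similarly, PCA is fit once on all drugs before cross-validation
(`pca_per_fold=True` gives the per-fold refit).

## The ten network features

Letter code D, W, E, O, C, B, A, H, T, P; fixed column order in
`NETWORK_FEATURE_COLUMNS`. Exactly W and P consume the normalised weights —
a contract enforced by test (permuting weights with fixed topology must
leave the other eight columns bit-identical).

| feature | definition | notes |
|---|---|---|
| degree | `deg(v)/(N−1)` | binary graph |
| weighted degree | `s(v) = Σ w(u,v)` | raw strength, not divided by `N−1`; dividing would only rescale a column that classifiers standardise implicitly and p-values ignore |
| eigenvector | principal eigenvector of binary adjacency, unit L2 norm | power iteration on `A + I`: same Perron vector, but immune to the sign oscillation plain iteration suffers on bipartite graphs whose extreme eigenvalues tie in magnitude |
| closeness | `(N−1)/Σ_u dist(v,u)` | unweighted BFS distances; Wasserman–Faust scaling `(r−1)²/((N−1)Σdist)` per component when disconnected |
| clustering | `2T(v)/(deg(v)(deg(v)−1))` | 0 when `deg < 2` |
| betweenness | Brandes accumulation, endpoints excluded | normalised by `2/((N−1)(N−2))`, so the middle of a 3-path scores exactly 1 |
| authority, hub | HITS with undirected edges as reciprocal directed pairs | one iteration applies a full round `a ← Aᵀh, h ← Aa` (power iteration with `A²`); since `AᵀA = AAᵀ` for symmetric `A` the two scores coincide, which the code asserts. Half-step updates would instead land on different odd/even-power limits on bipartite graphs, where `A²`'s top eigenvalue is degenerate |
| triangles | `diag(A³)/2` | integer count |
| weighted PageRank | `PR(v) = (1−d)/N + d Σ_u PR(u) w(u,v)/s(u)` | damping 0.85, L1 tolerance 1e−10, max 1000 iterations; zero-strength nodes (possible after min–max normalisation sets minimum-weight edges to 0) redistribute uniformly; scores sum to 1 |

Numerical defaults: power-iteration tolerance 1e−10 (max-norm), 1000
iterations, `ConvergenceError` carries the iteration count on failure.
On disconnected graphs the spectral scores (eigenvector, HITS) are computed
on the largest component with zeros elsewhere and a warning; closeness uses
the per-component scaled formula; global summary path statistics fall back
to the largest component and set a flag. These paths are exercised by unit
tests but not by the main pipeline, whose projected graphs are connected in
practice.

## Preprocessing

PCA is a mean-centred full SVD (deterministic solver); 10 components by
default. `components_for_threshold(model, 0.5)` supports choosing the
smallest count explaining half the variance. Note the threshold-to-count
mapping is data-dependent: on the 1/10-scale synthetic default (289 one-hot
columns) 10 components explain ~42% of the variance, not ~50% as on a full
2892-column encoding.

SMOTE is implemented from scratch: target minority count
`floor(sampling_ratio × n_majority)`, number created
`max(0, target − n_minority)`, each synthetic point `p + u(q − p)` with
`u ~ U[0,1]`, `p` a random minority row and `q` one of its `k = 5` nearest
minority neighbours (Euclidean; ties broken by lowest row index; `k` capped
at `n_minority − 1`). Originals are never altered; synthetics are appended
at the end, which is what lets tests assert that test folds contain no
synthetic rows. The canonical worked arithmetic — 61 positives, 771
negatives, ratio 0.43 — yields exactly `floor(0.43×771) − 61 = 270`
synthetic positives. (The count convention is sometimes quoted as
"771 × 0.43 − 1", which does not evaluate to 270; the floor convention is
the one consistent with the printed result and with common SMOTE
implementations, and is the one implemented.)

## Evaluation loop

Per eligible ADR (frequency ≥ 15, which with 10 folds leaves at least one
positive per test fold in most draws): seeded shuffled K-fold
(non-stratified by default, matching the "at least one positive in most
cases" behaviour; `stratified=True` available). Within each training fold,
if positives/negatives < 0.4 the fold is SMOTE-rebalanced with a
deterministic per-fold seed. AUROC is the Mann–Whitney rank statistic
(ties 0.5) of the classifier's scores on the untouched test fold; folds
whose test split holds one class contribute accuracy but no AUROC and are
counted. Accuracy uses the classifier's own 0.5-threshold prediction.

Classifiers: logistic regression (lbfgs, 1000 iters), decision tree
(library defaults), random forest (max depth 10), SVM (RBF,
decision-function scores), kNN (k = 5), single-hidden-layer neural network
(32 units, Adam), and gradient-boosted trees with a small fixed grid
(depth {3, 6} × learning rate {0.1, 0.3}, 3-fold inner CV).

Feature importance: per ADR, an unpenalised logistic regression on the full
20-feature set (SMOTE-balanced once for the whole set when the trigger rule
fires — the AUROC loop, by contrast, balances per fold). Wald p-values come
from the asymptotic covariance of a binomial GLM fitted by iteratively
reweighted least squares, which converges where a Newton logit fit diverges
on the near-separable fits these strong features produce; a
likelihood-ratio option (`method="lr"`) refits with single-feature
deletion. Perfect separation (fitted probabilities reproducing the labels)
is detected and the ADR excluded from the aggregate with a log entry, since
Wald statistics collapse there (Hauck–Donner).

## Synthetic data generator

The generator emulates the dependency structure the analysis exploits, not
pharmacology. `n_latent = 20` latent mechanisms have Zipf-decaying carry
probabilities (exponent 1.5, scaled so drugs carry 2 mechanisms on
average); each mechanism governs each ADR with probability 0.05 and each
feature column with probability 0.05. A drug is associated with an ADR with
probability `link_strength = 0.8` if any carried mechanism governs it, else
`adr_base_rate = 0.02`; feature bits governed by carried mechanisms are set
and every bit is flipped with probability `feature_noise` (0.05 by default;
`with_noise_features()` sets 0.5, making the descriptors pure noise).
Defaults mirror a 1/10-scale compendium: 200 drugs, 150 ADRs, block widths
(88, 11, 87, 17, 79, 7). The Zipf popularity is what produces the
heavy-tailed ADR frequency profile (median 7 vs mean ~18 drugs per ADR at
the defaults) and, downstream, a projected network in the observed regime
(density ≈ 0.96, average path length ≈ 1.04, clustering ≈ 0.98,
strength–PageRank correlation > 0.999).

What the generator does *not* emulate: real chemistry or dosage, ADR
category structure, reporting biases, or correlated noise across feature
blocks. Passing tests on this data therefore demonstrate that the pipeline
recovers planted relational signal under realistic sparsity and imbalance —
not that any particular AUROC level transfers to a real compendium.

Ground-truth mechanism assignments are emitted for diagnostics but no
pipeline stage reads them, preventing accidental leakage in tests.

## Problem sizes and stochastic margins

Tests and the acceptance script run the full pipeline at the 200 × 150
default with logistic regression and a two-step ladder (baseline vs all
ten features) — about 40 s — and verify centrality correctness against
independent reference computations on 50 random graphs of ≤ 30 nodes.
On planted-signal data the paired per-ADR AUROC gain is large and stable
(z between 6 and 8 across generator seeds). The *ordering* of the mean
p-values is the tightest property at this scale: weighted degree and
weighted PageRank are the two smallest at most seeds, but betweenness can
edge past them by ~0.01–0.04 on some draws; at full compendium scale
(hundreds of evaluated ADRs) the weight-aware features separate far more
sharply. The shipped acceptance test fixes the generator seed.

## Known limitations

- The evaluation inherits the original design's target-ADR leakage unless
  `holdout_adr_edges=True`; the two settings answer different questions.
- Wald p-values near separation are unstable even when flagged fits are
  excluded; the likelihood-ratio option is slower but better calibrated
  there.
- No weighted-shortest-path closeness/betweenness variants, no Katz or
  other centralities beyond the ten, no per-block PCA, and no ADR category
  hierarchies.
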