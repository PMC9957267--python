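"""Run the per-ADR evaluation loop on synthetic data with pure-noise drug
features and show that the network features carry the predictive signal.

For each ADR with at least 15 associated drugs, a logistic-regression
classifier is scored by 10-fold cross-validated AUROC on the PCA-only
baseline, on baseline+DW (degree + weighted degree), and on the full
20-feature set.  Wald p-values from an unpenalised logistic fit rank the
ten network features by importance.  Takes about a minute.
"""

import numpy as np

from adrnet import PipelineConfig, concat_one_hot, run_evaluation, simulate_dataset, SimulationConfig
from adrnet.synthetic_data import with_noise_features

config = with_noise_features(SimulationConfig(seed=1))  # features pure noise
dataset = simulate_dataset(config)

pipeline = PipelineConfig(
    feature_ladder=("", "DW", "DWEOCBAHTP"),
    classifiers=("LR",),
    seed=1,
)
report = run_evaluation(dataset.incidence, concat_one_hot(dataset.features), pipeline)

print("mean AUROC across eligible ADRs (logistic regression):")
print(report.ladder_table.round(3).to_string())

results = report.results
base = results[results["feature_set"] == ""].set_index("adr_id")["mean_auroc"]
full = results[results["feature_set"] == "DWEOCBAHTP"].set_index("adr_id")["mean_auroc"]
diffs = (full - base).dropna()
se = diffs.std(ddof=1) / np.sqrt(len(diffs))
print(f"\npaired AUROC gain over {len(diffs)} ADRs: "
      f"{diffs.mean():.3f} ± {se:.3f} (z = {diffs.mean() / se:.1f})")
print("A baseline near 0.5 is expected — the drug features are noise by "
      "construction — so the entire lift comes from the network features.")

print("\nmean Wald p-values per network feature (smaller = more important):")
print(report.pvalue_summary.sort_values("mean_p_value").round(4).to_string())
print("The two weight-aware features (weighted degree, weighted PageRank) "
      "rank at the top: the edge weights, not the topology, encode how "
      "strongly two drugs' ADR profiles overlap.")

print("\ntop 5 ADRs by AUROC with network features:")
print(report.adr_ranking.head(5).round(3).to_string(index=False))
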