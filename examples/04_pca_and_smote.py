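"""Reduce the one-hot drug features by PCA and rebalance a label with SMOTE.

PCA keeps 10 components (about half the variance of the one-hot encoding);
SMOTE synthesises minority examples on segments between a minority point
and one of its 5 nearest minority neighbours, targeting a minority count of
floor(0.43 x majority).
"""

import numpy as np

from adrnet import (
    SimulationConfig,
    SmoteConfig,
    components_for_threshold,
    concat_one_hot,
    fit_pca,
    simulate_dataset,
    smote_oversample,
    variance_curve,
)

dataset = simulate_dataset(SimulationConfig(seed=0))
onehot = concat_one_hot(dataset.features).to_numpy(dtype=float)

model = fit_pca(onehot, n_components=60)
curve = variance_curve(model)
print(f"one-hot width: {onehot.shape[1]} columns")
print(f"cumulative variance explained by 10 components: {curve[9]:.3f}")
print(f"components needed for 50% of the variance: "
      f"{components_for_threshold(model, 0.5)}")

# the canonical imbalance: 61 positives against 771 negatives, ratio 0.43
rng = np.random.default_rng(0)
x = rng.normal(size=(832, 10))
y = np.r_[np.ones(61, dtype=int), np.zeros(771, dtype=int)]
x_out, y_out = smote_oversample(x, y, SmoteConfig(k_neighbors=5, sampling_ratio=0.43, seed=0))
created = int(y_out.sum()) - 61
print(f"\nSMOTE on 61 positives / 771 negatives at ratio 0.43:")
print(f"  synthetic positives created: {created} "
      f"(floor(0.43 x 771) - 61 = {int(np.floor(0.43 * 771)) - 61})")
print(f"  dataset grows from {len(y)} to {len(y_out)} rows; "
      "originals are untouched and synthetics are appended at the end.")
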