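"""Synthetic drug–ADR datasets with planted latent mechanisms.

Real drug–ADR compendia (hundreds of drugs, >1000 ADRs, six one-hot feature
categories) are not redistributable, so this module generates datasets with
the statistical structure the downstream analysis exploits:

* a binary drug × ADR incidence matrix whose per-ADR frequencies are
  right-skewed (many rare ADRs, a few very common ones);
* six binary feature blocks of configurable widths;
* a planted set of latent "mechanisms" — shared biological causes — such
  that drugs carrying the same mechanism tend to share both ADRs and
  feature bits.  Mechanism popularity follows a Zipf-like law, which is
  what produces the heavy-tailed ADR frequency distribution.

The ground-truth drug → mechanism assignment is emitted for diagnostics but
is never consumed by any pipeline stage.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset_io import (
    BLOCK_NAMES,
    FeatureBlock,
    FeatureBlockSet,
    IncidenceMatrix,
    write_feature_block,
    write_incidence,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset", "frequency_profile", "save_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the latent-mechanism generator.

    Defaults mirror a 1/10-scale version of an integrated 832-drug / 2892-
    feature / 1385-ADR compendium: 200 drugs, 150 ADRs and block widths
    (88, 11, 87, 17, 79, 7).

    Parameters
    ----------
    n_latent
        Number of latent mechanisms (shared causes).
    adr_base_rate
        Probability of a drug–ADR association with no mechanistic cause
        (background noise in the compendium).
    link_strength
        Probability that a mechanism carried by a drug activates each ADR
        it governs; must dominate ``adr_base_rate`` for signal to exist.
    feature_noise
        Independent flip probability applied to every feature bit; 0.5
        renders the feature blocks pure noise.
    zipf_exponent
        Exponent of the Zipf-like mechanism-popularity law; larger values
        concentrate drugs on few mechanisms (heavier frequency tail).
    mean_mechanisms
        Target mean number of mechanisms carried per drug.
    adr_govern_prob, feature_govern_prob
        Probability that a given mechanism governs a given ADR / feature
        column.
    """

    n_drugs: int = 200
    n_adrs: int = 150
    block_widths: tuple[int, ...] = (88, 11, 87, 17, 79, 7)
    n_latent: int = 20
    adr_base_rate: float = 0.02
    link_strength: float = 0.8
    feature_noise: float = 0.05
    zipf_exponent: float = 1.5
    mean_mechanisms: float = 2.0
    adr_govern_prob: float = 0.05
    feature_govern_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_adrs", "n_latent"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.block_widths) != 6:
            raise ValueError("block_widths must have exactly 6 entries")
        if any(int(w) < 1 for w in self.block_widths):
            raise ValueError("block widths must be >= 1")
        for name in ("adr_base_rate", "link_strength", "feature_noise",
                     "adr_govern_prob", "feature_govern_prob"):
            p = float(getattr(self, name))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_latent > self.n_adrs:
            raise ValueError(
                f"n_latent ({self.n_latent}) > n_adrs ({self.n_adrs}): "
                "degenerate design with more mechanisms than ADRs"
            )


@dataclass
class SyntheticDataset:
    incidence: IncidenceMatrix
    features: FeatureBlockSet
    #: ground truth: drug id -> sorted list of latent mechanism indices.
    #: Diagnostics only; no pipeline stage reads it.
    latent_assignment: dict[str, list[int]] = field(default_factory=dict)


def _mechanism_popularity(config: SimulationConfig) -> np.ndarray:
    """Zipf-like per-mechanism carry probabilities, scaled to the target mean."""
    ranks = np.arange(1, config.n_latent + 1, dtype=float)
    weights = ranks ** (-config.zipf_exponent)
    probs = weights * (config.mean_mechanisms / weights.sum())
    return np.clip(probs, 0.0, 1.0)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset; bitwise deterministic for a fixed config/seed.

    Each mechanism governs a random subset of ADRs and of feature columns.
    Each drug carries mechanism *m* independently with a Zipf-decaying
    probability (drugs left with no mechanism are assigned one drawn from
    the popularity law, so every drug has at least one cause).  Drug *d* is
    associated with ADR *a* with probability ``link_strength`` if any of
    *d*'s mechanisms governs *a*, else ``adr_base_rate``.  Feature columns
    governed by a drug's mechanisms are set to 1, then every bit is flipped
    independently with probability ``feature_noise``.
    """
    rng = np.random.default_rng(config.seed)
    n_d, n_a, n_l = config.n_drugs, config.n_adrs, config.n_latent
    total_width = int(sum(config.block_widths))

    popularity = _mechanism_popularity(config)
    drug_mech = rng.random((n_d, n_l)) < popularity
    empty = ~drug_mech.any(axis=1)
    if empty.any():
        forced = rng.choice(n_l, size=int(empty.sum()), p=popularity / popularity.sum())
        drug_mech[np.flatnonzero(empty), forced] = True

    mech_adr = rng.random((n_l, n_a)) < config.adr_govern_prob
    mech_feat = rng.random((n_l, total_width)) < config.feature_govern_prob

    governed_adr = drug_mech @ mech_adr  # bool: any carried mechanism governs ADR
    prob = np.where(governed_adr, config.link_strength, config.adr_base_rate)
    incidence_values = (rng.random((n_d, n_a)) < prob).astype(np.int8)

    feat_base = drug_mech @ mech_feat
    flips = rng.random((n_d, total_width)) < config.feature_noise
    feat_values = (feat_base ^ flips).astype(np.int8)

    drug_ids = [f"D{i + 1:04d}" for i in range(n_d)]
    adr_ids = [f"ADR{j + 1:04d}" for j in range(n_a)]
    incidence = IncidenceMatrix(drug_ids, adr_ids, incidence_values)

    blocks, offset = [], 0
    for name, width in zip(BLOCK_NAMES, config.block_widths):
        width = int(width)
        cols = [f"{name}_{k + 1:04d}" for k in range(width)]
        blocks.append(FeatureBlock(name, cols, feat_values[:, offset:offset + width]))
        offset += width
    features = FeatureBlockSet(list(drug_ids), blocks)

    assignment = {
        drug_ids[i]: sorted(int(m) for m in np.flatnonzero(drug_mech[i]))
        for i in range(n_d)
    }
    return SyntheticDataset(incidence, features, assignment)


def frequency_profile(incidence: IncidenceMatrix) -> pd.Series:
    """Per-ADR drug counts (column sums); their total equals the number of
    1-entries in the incidence matrix."""
    counts = incidence.values.sum(axis=0)
    return pd.Series(counts, index=incidence.adr_ids, name="n_drugs")


def save_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write incidence + blocks as TSV and the ground truth as JSON."""
    os.makedirs(out_dir, exist_ok=True)
    write_incidence(dataset.incidence, os.path.join(out_dir, "incidence.tsv"))
    for block in dataset.features.blocks:
        write_feature_block(
            dataset.features.drug_ids, block, os.path.join(out_dir, f"features_{block.name}.tsv")
        )
    with open(os.path.join(out_dir, "latent_assignment.json"), "w") as fh:
        json.dump(dataset.latent_assignment, fh, indent=0)


def with_noise_features(config: SimulationConfig) -> SimulationConfig:
    """The same study conditions but with pure-noise feature blocks
    (flip probability 0.5), used to isolate the network features' signal."""
    return replace(config, feature_noise=0.5)
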