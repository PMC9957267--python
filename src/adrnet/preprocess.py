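"""Dimensionality reduction and class rebalancing.

The 2892-wide one-hot drug representation is reduced by PCA to 10
components (chosen to explain roughly half the variance).  Per-ADR labels
are severely imbalanced, so training folds are rebalanced with SMOTE:
synthetic minority samples interpolated between a minority point and one of
its k nearest minority neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "PCAModel",
    "SmoteConfig",
    "fit_pca",
    "transform_pca",
    "variance_curve",
    "components_for_threshold",
    "smote_oversample",
    "smote_count",
]


@dataclass
class PCAModel:
    """Fitted principal-component basis.

    ``components`` rows are mutually orthonormal directions ordered by
    decreasing explained variance; ``explained_variance_ratio`` entries are
    non-increasing and sum to at most 1.
    """

    mean_vector: np.ndarray
    components: np.ndarray  # (k, p)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(x: np.ndarray, n_components: int = 10) -> PCAModel:
    """Mean-centred SVD fit via a full (deterministic) solver."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs a 2-d matrix with at least 2 rows")
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_rows, n_cols)={min(x.shape)}"
        )
    sk = _SkPCA(n_components=n_components, svd_solver="full").fit(x)
    return PCAModel(sk.mean_.copy(), sk.components_.copy(), sk.explained_variance_ratio_.copy())


def transform_pca(model: PCAModel, x: np.ndarray, drug_ids=None) -> pd.DataFrame:
    """Centred projection onto the fitted components.

    Returns a DataFrame with columns ``pc01 .. pcK`` indexed by ``drug_ids``
    (or the row number when not given).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"input has {x.shape[-1] if x.ndim == 2 else '?'} columns, "
            f"model expects {model.mean_vector.shape[0]}"
        )
    scores = (x - model.mean_vector) @ model.components.T
    cols = [f"pc{k + 1:02d}" for k in range(model.n_components)]
    index = drug_ids if drug_ids is not None else range(x.shape[0])
    return pd.DataFrame(scores, index=index, columns=cols)


def variance_curve(model: PCAModel) -> np.ndarray:
    """Cumulative explained-variance ratio per component count (1-based)."""
    return np.cumsum(model.explained_variance_ratio)


def components_for_threshold(model: PCAModel, threshold: float = 0.5) -> int:
    """Smallest component count whose cumulative ratio reaches ``threshold``."""
    curve = variance_curve(model)
    idx = np.searchsorted(curve, threshold)
    if idx >= len(curve):
        raise ValueError(
            f"model explains only {curve[-1]:.3f} of variance, below threshold {threshold}"
        )
    return int(idx) + 1


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE settings: k nearest minority neighbours, the target
    minority/majority sampling ratio, and the imbalance ratio below which
    rebalancing is triggered at all."""

    k_neighbors: int = 5
    sampling_ratio: float = 0.43
    trigger_ratio: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.sampling_ratio <= 0 or self.trigger_ratio <= 0:
            raise ValueError("ratios must be positive")


def smote_count(n_minority: int, n_majority: int, sampling_ratio: float) -> int:
    """Number of synthetic minority samples to create:
    max(0, floor(sampling_ratio · n_majority) − n_minority)."""
    return max(0, math.floor(sampling_ratio * n_majority) - n_minority)


def smote_oversample(
    x: np.ndarray, y: np.ndarray, config: SmoteConfig
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling of the positive (minority) class.

    Each synthetic point is ``p + u·(q − p)`` with ``u ~ U[0, 1]``, ``p`` a
    randomly chosen minority point and ``q`` one of its k nearest minority
    neighbours (Euclidean distance, ties broken by lowest row index; k is
    capped at n_minority − 1).  Original rows are returned unchanged and in
    place; synthetic rows are appended at the end with label 1.
    Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    minority = np.flatnonzero(y == 1)
    majority = np.flatnonzero(y == 0)
    n_create = smote_count(len(minority), len(majority), config.sampling_ratio)
    if n_create == 0:
        return x.copy(), y.copy()
    if len(minority) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples (no neighbour exists)")

    xm = x[minority]
    k = min(config.k_neighbors, len(minority) - 1)
    dists = cdist(xm, xm)
    np.fill_diagonal(dists, np.inf)
    # stable argsort => ties broken by lowest row index
    nn = np.argsort(dists, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, len(minority), size=n_create)
    pick = rng.integers(0, k, size=n_create)
    u = rng.random(n_create)
    p = xm[base]
    q = xm[nn[base, pick]]
    synth = p + u[:, None] * (q - p)

    x_out = np.vstack([x, synth])
    y_out = np.concatenate([y, np.ones(n_create, dtype=int)])
    return x_out, y_out
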