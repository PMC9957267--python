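"""Reading, validating and assembling drug–ADR matrices and drug feature blocks.

The pipeline's root inputs are a binary drug × ADR incidence matrix and six
binary drug-feature blocks (chemical, enzyme, indication, pathway, target,
transporter).  All are exchanged as delimited text matrices with a header row
of column identifiers and a first column of drug identifiers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "IncidenceMatrix",
    "FeatureBlock",
    "FeatureBlockSet",
    "BLOCK_NAMES",
    "read_incidence",
    "read_feature_block",
    "write_incidence",
    "write_feature_block",
    "concat_one_hot",
]

#: canonical block order for the six drug feature categories
BLOCK_NAMES = ("chemical", "enzyme", "indication", "pathway", "target", "transporter")


class ValidationError(ValueError):
    """Raised when an input matrix violates the binary/uniqueness contract."""


def _check_binary(values: np.ndarray, row_ids, col_ids, what: str) -> np.ndarray:
    arr = np.asarray(values)
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} entry at row '{row_ids[i]}', column '{col_ids[j]}' is "
            f"{arr[i, j]!r}; entries must be 0 or 1"
        )
    return arr.astype(np.int8)


def _check_unique(ids, what: str) -> list:
    ids = [str(x) for x in ids]
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: '{x}'")
        seen.add(x)
    return ids


@dataclass
class IncidenceMatrix:
    """Binary drug × ADR association table.

    ``values[i, j] == 1`` iff drug ``drug_ids[i]`` is associated with ADR
    ``adr_ids[j]``.  Row/column order is preserved from the source.
    """

    drug_ids: list[str]
    adr_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.adr_ids = _check_unique(self.adr_ids, "ADR")
        if len(self.drug_ids) == 0 or len(self.adr_ids) == 0:
            raise ValidationError("incidence matrix needs at least one drug and one ADR")
        self.values = _check_binary(self.values, self.drug_ids, self.adr_ids, "incidence")
        if self.values.shape != (len(self.drug_ids), len(self.adr_ids)):
            raise ValidationError(
                f"incidence shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.adr_ids)} ADRs"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_adrs(self) -> int:
        return len(self.adr_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.adr_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IncidenceMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


@dataclass
class FeatureBlock:
    """One named binary feature category (e.g. ``"target"``) for all drugs."""

    name: str
    column_ids: list[str]
    values: np.ndarray  # drugs x width, rows aligned with the owning set

    def __post_init__(self) -> None:
        self.column_ids = _check_unique(self.column_ids, f"{self.name} column")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_ids):
            raise ValidationError(
                f"block '{self.name}' has {self.values.shape[1]} columns but "
                f"{len(self.column_ids)} column identifiers"
            )

    @property
    def width(self) -> int:
        return len(self.column_ids)


@dataclass
class FeatureBlockSet:
    """Ordered collection of feature blocks sharing one drug ordering."""

    drug_ids: list[str]
    blocks: list[FeatureBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        names = _check_unique([b.name for b in self.blocks], "block")
        del names
        for b in self.blocks:
            if b.values.shape[0] != len(self.drug_ids):
                raise ValidationError(
                    f"block '{b.name}' has {b.values.shape[0]} rows for "
                    f"{len(self.drug_ids)} drugs"
                )
            b.values = _check_binary(b.values, self.drug_ids, b.column_ids, f"block '{b.name}'")

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    @property
    def total_width(self) -> int:
        return sum(b.width for b in self.blocks)

    @classmethod
    def from_frames(cls, frames: list[tuple[str, pd.DataFrame]]) -> "FeatureBlockSet":
        """Assemble from per-block DataFrames, enforcing one shared drug order."""
        if not frames:
            raise ValidationError("no feature blocks given")
        ref = list(frames[0][1].index.map(str))
        blocks = []
        for name, fr in frames:
            if list(fr.index.map(str)) != ref:
                raise ValidationError(
                    f"block '{name}' drug ordering differs from block '{frames[0][0]}'"
                )
            blocks.append(FeatureBlock(name, list(fr.columns.map(str)), fr.to_numpy()))
        return cls(ref, blocks)


# ---------------------------------------------------------------------------
# delimited text I/O


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def _read_matrix(path, delimiter: str | None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    return frame


def read_incidence(path, delimiter: str | None = None) -> IncidenceMatrix:
    """Read and validate a drug × ADR incidence matrix.

    The delimiter is inferred from the extension (``.csv`` comma, anything
    else tab) unless given explicitly.
    """
    return IncidenceMatrix.from_frame(_read_matrix(path, delimiter))


def read_feature_block(path, name: str, delimiter: str | None = None) -> FeatureBlock:
    frame = _read_matrix(path, delimiter)
    return FeatureBlock(name, list(frame.columns), frame.to_numpy())


def write_incidence(incidence: IncidenceMatrix, path, delimiter: str | None = None) -> None:
    incidence.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter))


def write_feature_block(
    drug_ids: list[str], block: FeatureBlock, path, delimiter: str | None = None
) -> None:
    frame = pd.DataFrame(block.values, index=drug_ids, columns=block.column_ids)
    frame.to_csv(path, sep=_delimiter_for(path, delimiter))


def concat_one_hot(features: FeatureBlockSet) -> pd.DataFrame:
    """Horizontally concatenate the feature blocks into one one-hot matrix.

    Returns a drugs × total_width DataFrame whose columns are a MultiIndex
    ``(block_name, column_id)`` so every column's provenance is retained.
    Blocks are concatenated in their stored (canonical) order.
    """
    if not features.blocks:
        raise ValidationError("feature block set is empty")
    parts = []
    for b in features.blocks:
        cols = pd.MultiIndex.from_product([[b.name], b.column_ids], names=["block", "column"])
        parts.append(pd.DataFrame(b.values, index=features.drug_ids, columns=cols))
    return pd.concat(parts, axis=1)
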