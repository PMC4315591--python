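"""Core value types shared across pipeline stages.

An :class:`ExpressionMatrix` is a rectangular gene-by-sample table carrying
an explicit scale flag (``linear`` intensities or ``log2`` values); a
:class:`DesignTable` maps every sample to one of the four experimental
conditions and a replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default condition labels, in canonical order: JNK-positive / JNK-negative
#: cells from wounded ("W") and non-wounded discs.
CONDITIONS = ("JNK+W", "JNK-W", "JNK+", "JNK-")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """Gene/probe × sample matrix with a scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe id, columns are sample ids.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValidationError(f"missing values in column {bad!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate sample ids")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValidationError("negative values in a linear-scale matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_log2(self, pseudo: float = 1.0) -> "ExpressionMatrix":
        """Return the matrix on log2 scale (identity if already log2)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values + pseudo), scale="log2")


@dataclass
class DesignTable:
    """Sample → (condition, replicate) assignment for a 4-condition design."""

    table: pd.DataFrame  # columns: sample, condition, replicate
    conditions: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        required = {"sample", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table lacks columns {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"sample {dup!r} appears twice in design")
        unknown = set(self.table["condition"]) - set(self.conditions)
        if unknown:
            raise ValidationError(f"unknown condition labels {sorted(unknown)}")

    def samples_for(self, condition: str) -> list[str]:
        sub = self.table[self.table["condition"] == condition]
        return list(sub["sample"])

    def n_replicates(self, condition: str) -> int:
        return len(self.samples_for(condition))

    def validate_against(self, m: ExpressionMatrix) -> None:
        """Check every matrix sample is designed and ≥2 replicates/condition."""
        designed = set(self.table["sample"])
        matrix = set(m.samples)
        missing = matrix - designed
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")
        for cond in self.conditions:
            if self.n_replicates(cond) < 2:
                raise ValidationError(
                    f"condition {cond!r} has fewer than 2 replicates"
                )
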