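"""In-memory containers shared across pipeline stages.

The pipeline's sole raw input is a gene x sample integer count matrix with a
two-level condition label per sample (reference first, conventionally CON,
treatment second, conventionally VTM). The condition order is never inferred
from the data: callers (or the pipeline config) state which level is the
reference.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


def _check_two_levels(conditions: pd.Series, levels: tuple[str, str] | None) -> tuple[str, str]:
    uniq = sorted(map(str, pd.unique(conditions)))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two condition levels, found {uniq}")
    if levels is None:
        levels = (uniq[0], uniq[1])
    else:
        levels = (str(levels[0]), str(levels[1]))
        if sorted(levels) != uniq:
            raise ValueError(f"declared levels {levels} do not match data levels {uniq}")
    return levels


@dataclasses.dataclass
class CountMatrix:
    """Raw integer counts (genes as rows) plus per-sample condition labels.

    Parameters
    ----------
    counts
        Gene x sample DataFrame of non-negative integers; unique gene and
        sample ids.
    conditions
        Sample -> condition label. Every sample column must be present;
        exactly two levels with >= 2 samples each.
    levels
        ``(reference, treatment)`` order of the two condition levels. If
        omitted, the alphabetically first level is taken as reference.
    """

    counts: pd.DataFrame
    conditions: pd.Series
    levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        self.conditions = self.conditions.loc[self.counts.columns].astype(str)
        self.levels = _check_two_levels(self.conditions, self.levels)
        for lev in self.levels:
            n = int((self.conditions == lev).sum())
            if n < 2:
                raise ValueError(f"condition {lev!r} has {n} sample(s); need >= 2")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, level: str) -> list[str]:
        return list(self.conditions.index[self.conditions == level])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.conditions.copy(), self.levels)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclasses.dataclass
class ExpressionMatrix:
    """Variance-stabilized expression on the same shape contract as its source counts."""

    values: pd.DataFrame
    conditions: pd.Series
    levels: tuple[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.conditions = self.conditions.loc[self.values.columns].astype(str)
        self.levels = _check_two_levels(self.conditions, self.levels)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_of(self, level: str) -> list[str]:
        return list(self.conditions.index[self.conditions == level])

    def condition_values(self, level: str) -> pd.DataFrame:
        return self.values[self.samples_of(level)]
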