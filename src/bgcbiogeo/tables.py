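"""Shared tabular containers for count and abundance data.

Two containers travel through most of the pipeline:

* :class:`CountMatrix` — estimated read counts per biosynthetic gene
  cluster (BGC, rows) and metagenome sample (columns), together with
  per-sample size factors and a small state machine tracking whether the
  counts are raw, pseudocounted, or size-factor normalized.
* :class:`TaxaTable` — per-sample species relative abundances (the
  MetaPhlAn-style community profile) plus the post-QC read total of each
  sample, which is needed to convert relative abundances back into
  estimated read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "TaxaTable"]


@dataclass
class CountMatrix:
    """Samples x BGCs count container (stored BGCs-as-rows).

    Parameters
    ----------
    counts
        DataFrame with BGC ids as the index and sample ids as columns.
    state
        One of ``"raw"``, ``"pseudocounted"``, ``"normalized"``.
    size_factors
        Per-sample positive scaling constants (median-of-ratios), set by
        :func:`bgcbiogeo.quantify.size_factor_normalize`.
    normalized
        Size-factor normalized counts, present only in state
        ``"normalized"``.
    """

    counts: pd.DataFrame
    state: str = "raw"
    size_factors: Optional[pd.Series] = None
    normalized: Optional[pd.DataFrame] = None
    dropped_undetected: int = 0

    def __post_init__(self) -> None:
        if self.state not in {"raw", "pseudocounted", "normalized"}:
            raise ValueError(f"unknown CountMatrix state: {self.state!r}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def bgcs(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def values_for_analysis(self) -> pd.DataFrame:
        """Normalized counts if available, otherwise the stored counts."""
        if self.state == "normalized":
            assert self.normalized is not None
            return self.normalized
        return self.counts

    def to_tsv(self, counts_path, size_factor_path=None) -> None:
        self.values_for_analysis().to_csv(counts_path, sep="\t")
        if size_factor_path is not None and self.size_factors is not None:
            self.size_factors.rename("size_factor").to_csv(
                size_factor_path, sep="\t", index_label="sample_id"
            )


@dataclass
class TaxaTable:
    """Per-sample species relative abundances plus post-QC read totals.

    ``abundances`` has sample ids as the index and species as columns;
    values are relative abundances in [0, 1] and rows sum to at most 1
    (a row may sum to less than 1 if some reads were unclassified).
    """

    abundances: pd.DataFrame
    total_reads: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        if (ab < 0).any() or (ab > 1 + 1e-9).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        row_sums = ab.sum(axis=1)
        if (row_sums > 1 + 1e-6).any():
            raise ValueError("per-sample relative abundances sum to > 1")
        if self.total_reads is not None:
            self.total_reads = self.total_reads.reindex(self.abundances.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundances.columns)

    def to_tsv(self, path) -> None:
        self.abundances.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, total_reads: Optional[pd.Series] = None) -> "TaxaTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(abundances=df, total_reads=total_reads)
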