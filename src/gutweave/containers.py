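"""Core tabular containers shared across pipeline layers.

The microbiome layer revolves around a taxa × samples integer count matrix
with per-sample metadata (diet, timepoint, source).  Both are held as pandas
objects so that standard I/O, alignment and group-by machinery apply; the
wrapper only enforces the invariants the downstream statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("diet", "timepoint", "source")


@dataclass
class CountTable:
    """Integer taxa × samples matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame with taxa as rows and samples as columns; non-negative
        integers.
    metadata
        DataFrame indexed by sample id with at least ``diet``, ``timepoint``
        and ``source`` columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        # align metadata rows to count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def taxa(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples) -> "CountTable":
        samples = list(samples)
        return CountTable(self.counts[samples].copy(), self.metadata.loc[samples].copy())

    def group_labels(self, by=("diet", "timepoint")) -> pd.Series:
        """Per-sample composite group label, e.g. ``control@68``."""
        parts = [self.metadata[c].astype(str) for c in by]
        out = parts[0]
        for p in parts[1:]:
            out = out + "@" + p
        return out

    def relative_abundance(self) -> "AbundanceTable":
        totals = self.sample_totals()
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.div(totals, axis=1)
        empty = totals[totals == 0].index.tolist()
        rel[empty] = 0.0
        return AbundanceTable(rel, self.metadata.copy(), empty_samples=empty)


@dataclass
class AbundanceTable:
    """Relative abundances on the same axes as the source :class:`CountTable`.

    Columns sum to 1 except all-zero samples, which are listed in
    ``empty_samples`` and left at zero.
    """

    abundances: pd.DataFrame
    metadata: pd.DataFrame
    empty_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.abundances.sum(axis=0)
        nonempty = [s for s in self.abundances.columns if s not in self.empty_samples]
        bad = [s for s in nonempty if abs(sums[s] - 1.0) > 1e-9]
        if bad:
            raise ValueError(f"abundance columns do not sum to 1: {bad}")
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def samples(self) -> list:
        return list(self.abundances.columns)

    def group_labels(self, by=("diet", "timepoint")) -> pd.Series:
        parts = [self.metadata[c].astype(str) for c in by]
        out = parts[0]
        for p in parts[1:]:
            out = out + "@" + p
        return out
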