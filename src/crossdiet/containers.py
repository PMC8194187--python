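"""Core in-memory containers shared across the package.

Tables are thin wrappers around :class:`pandas.DataFrame` so the usual
pandas machinery (indexing, joins, I/O) stays available, while the wrapper
enforces the domain invariants: non-negative integer counts, unique sample
IDs, simplex-valued composition rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column names of a sample mapping file, in on-disk order.
METADATA_COLUMNS = ["SampleID", "DogID", "Group", "Period", "Diet"]

#: Label used for features whose lineage lacks the requested rank.
UNASSIGNED = "Unassigned"

#: Label of the residual category appended by ``top_k_with_other``.
OTHER = "OTHER"


@dataclass
class CountTable:
    """Integer feature-by-sample abundance table with per-feature taxonomy.

    Parameters
    ----------
    counts
        DataFrame with feature IDs as the index and sample IDs as columns;
        values must be non-negative integers.
    taxonomy
        Series mapping each feature ID to a semicolon-delimited
        Greengenes-style lineage string (``k__...; p__...; f__...``).
        Missing entries are treated as unassigned.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.counts.index, dtype=object)
        self.taxonomy = self.taxonomy.reindex(self.counts.index).fillna("")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.taxonomy.equals(other.taxonomy)


@dataclass
class CompositionTable:
    """Simplex-valued sample-by-category proportion table.

    Rows (samples) sum to one within ``atol``; categories are taxa at a
    single rank, possibly ending in the residual ``OTHER`` category.
    """

    proportions: pd.DataFrame
    atol: float = 1e-9

    def __post_init__(self) -> None:
        values = self.proportions.to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError("empty composition table")
        if (values < 0).any() or (values > 1).any():
            raise ValueError("proportions must lie in [0, 1]")
        sums = values.sum(axis=1)
        bad = ~np.isclose(sums, 1.0, atol=self.atol, rtol=0.0)
        if bad.any():
            which = list(self.proportions.index[bad][:5])
            raise ValueError(f"rows do not sum to 1 (e.g. {which})")
        self.proportions = self.proportions.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def categories(self) -> list[str]:
        return list(self.proportions.columns)

    def is_strictly_positive(self) -> bool:
        return bool((self.proportions.to_numpy() > 0).all())


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata frame and return it indexed by SampleID.

    Accepts either a frame with a ``SampleID`` column or one already
    indexed by sample ID.
    """
    meta = metadata.copy()
    if "SampleID" in meta.columns:
        meta = meta.set_index("SampleID")
    missing = [c for c in METADATA_COLUMNS[1:] if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.duplicated().any():
        raise ValueError("duplicate SampleIDs in metadata")
    return meta
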