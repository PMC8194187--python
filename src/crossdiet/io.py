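"""Readers and writers for the plain-text interchange formats.

Feature tables use the QIIME-classic layout: a tab-separated file whose
header line starts with ``#OTU ID``, one column per sample, and a trailing
``taxonomy`` column holding the Greengenes lineage string. Mapping files
are tab-separated with a ``#SampleID`` header. Distance matrices are
square TSV with sample IDs on both margins.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import METADATA_COLUMNS, CountTable, validate_metadata


def write_feature_table(table: CountTable, path: str | os.PathLike) -> Path:
    """Write a QIIME-classic TSV feature table (with taxonomy column)."""
    path = Path(path)
    if table.counts.shape[1] == 0 or table.counts.shape[0] == 0:
        raise ValueError(f"refusing to write empty feature table to {path}")
    out = table.counts.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy)
    try:
        with open(path, "w") as handle:
            handle.write("#OTU ID\t" + "\t".join(map(str, out.columns)) + "\n")
            out.to_csv(handle, sep="\t", header=False)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing feature table to {path}: {exc}") from exc
    return path


def read_feature_table(path: str | os.PathLike) -> CountTable:
    """Read a QIIME-classic TSV feature table."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
    frame.index.name = None
    if "taxonomy" in frame.columns:
        taxonomy = frame.pop("taxonomy").fillna("")
    else:
        taxonomy = pd.Series("", index=frame.index, dtype=object)
    counts = frame.astype(float)
    return CountTable(counts=counts, taxonomy=taxonomy)


def write_mapping_file(metadata: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a sample mapping file (``#SampleID  DogID  Group  Period  Diet``)."""
    path = Path(path)
    meta = validate_metadata(metadata).reset_index()
    meta.columns = ["SampleID"] + list(meta.columns[1:])
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    meta = meta[cols + [c for c in meta.columns if c not in cols]]
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(meta.columns) + "\n")
        meta.to_csv(handle, sep="\t", header=False, index=False)
    return path


def read_mapping_file(path: str | os.PathLike) -> pd.DataFrame:
    """Read a mapping file; returns a frame indexed by SampleID."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    return validate_metadata(frame)


def write_distance_matrix(dm: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a square distance matrix as TSV with ``%.10g`` precision."""
    path = Path(path)
    dm.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_distance_matrix(path: str | os.PathLike) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col=0)
    dm.columns = dm.columns.astype(str)
    dm.index = dm.index.astype(str)
    if list(dm.index) != list(dm.columns):
        raise ValueError(f"distance matrix in {path} is not square/aligned")
    return dm.astype(float)


def write_key_value(mapping: dict, path: str | os.PathLike) -> Path:
    """Write a flat key/value sidecar (one ``key<TAB>value`` pair per line).

    Array-valued entries are flattened with comma separators so the file
    stays greppable plain text.
    """
    path = Path(path)
    with open(path, "w") as handle:
        for key, value in mapping.items():
            if isinstance(value, (list, tuple, np.ndarray)):
                text = ",".join(repr(v) if isinstance(v, str) else f"{v:.17g}"
                                if isinstance(v, (int, float, np.floating, np.integer))
                                else str(v) for v in np.asarray(value).ravel())
            else:
                text = str(value)
            handle.write(f"{key}\t{text}\n")
    return path


def read_key_value(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("\t")
            out[key] = value
    return out
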