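"""Rank aggregation and compositional preparation of count tables.

Turns OTU-level counts into the tables the downstream analyses consume:
counts aggregated to phylum/family/genus, relative abundances on the
simplex, median/range group summaries, the top-K + OTHER reduction used
for the family-level model, zero adjustment (the Dirichlet likelihood is
undefined on the simplex boundary), and per-sample genus ratios such as
Prevotella/Bacteroides.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .containers import OTHER, UNASSIGNED, CompositionTable, CountTable, validate_metadata

logger = logging.getLogger(__name__)

#: Greengenes rank prefixes.
RANK_PREFIX = {"kingdom": "k__", "phylum": "p__", "class": "c__",
               "order": "o__", "family": "f__", "genus": "g__",
               "species": "s__"}

_AGGREGATION_RANKS = ("phylum", "family", "genus")


def parse_rank(lineage: str, rank: str) -> str:
    """Extract the taxon name at ``rank`` from a Greengenes lineage string.

    Returns ``Unassigned`` when the rank label is absent or empty.
    """
    prefix = RANK_PREFIX[rank]
    for part in re.split(r";\s*", lineage or ""):
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            return name if name else UNASSIGNED
    return UNASSIGNED


def aggregate_taxa(table: CountTable, rank: str) -> CountTable:
    """Sum feature counts over taxa sharing the same label at ``rank``.

    Features lacking the rank label are pooled under ``Unassigned``;
    per-sample totals are conserved exactly.
    """
    if rank not in _AGGREGATION_RANKS:
        raise ValueError(f"rank must be one of {_AGGREGATION_RANKS}, got {rank!r}")
    labels = table.taxonomy.map(lambda s: parse_rank(s, rank))
    grouped = table.counts.groupby(labels.to_numpy()).sum()
    grouped = grouped.sort_index()
    taxonomy = pd.Series({name: name for name in grouped.index}, dtype=object)
    return CountTable(counts=grouped, taxonomy=taxonomy)


def relative_abundance(table: CountTable) -> CompositionTable:
    """Convert counts to per-sample proportions (samples as rows)."""
    totals = table.sample_totals
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    props = (table.counts / totals).T
    return CompositionTable(proportions=props)


def summarize_group(
    composition: CompositionTable,
    metadata: pd.DataFrame,
    group_by: str,
) -> pd.DataFrame:
    """Median and range of each category's proportion within each group.

    Median uses the midpoint convention for even group sizes. Groups with
    no samples present in the composition table are omitted with a
    warning. Returns a long-format frame with columns
    ``group, category, median, min, max``.
    """
    meta = validate_metadata(metadata)
    if group_by not in meta.columns:
        raise ValueError(f"metadata has no column {group_by!r}")
    props = composition.proportions
    rows = []
    for group, sample_ids in meta.groupby(group_by, sort=True).groups.items():
        present = [s for s in sample_ids if s in props.index]
        if not present:
            logger.warning("WARN group %r=%r has no samples in table; omitted",
                           group_by, group)
            continue
        block = props.loc[present]
        for category in props.columns:
            col = block[category]
            rows.append({"group": group, "category": category,
                         "median": float(col.median()),
                         "min": float(col.min()), "max": float(col.max())})
    return pd.DataFrame(rows, columns=["group", "category", "median", "min", "max"])


def top_k_with_other(composition: CompositionTable, k: int = 20) -> CompositionTable:
    """Keep the ``k`` most abundant categories and pool the rest as OTHER.

    Abundance ranking is by mean proportion across samples (ties broken
    by category name for determinism); retained categories are ordered by
    decreasing mean. OTHER is the per-sample residual ``1 - sum(kept)``,
    so rows still sum to one exactly. If ``k`` meets or exceeds the number
    of categories, all are retained and OTHER is identically ~0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    props = composition.proportions
    means = props.mean(axis=0)
    if k >= len(means):
        if k > len(means):
            logger.warning("WARN top-k=%d exceeds %d categories; retaining all",
                           k, len(means))
        k = len(means)
    # ties broken alphabetically: stable mergesort on name-sorted means
    ranked = means.sort_index().sort_values(ascending=False, kind="mergesort")
    keep = list(ranked.index[:k])
    kept = props[keep].copy()
    other = (1.0 - kept.sum(axis=1)).clip(lower=0.0)
    kept[OTHER] = other
    kept = kept.div(kept.sum(axis=1), axis=0)  # absorb 1e-16 rounding
    return CompositionTable(proportions=kept)


def adjust_zeros(composition: CompositionTable, epsilon: float = 1e-6) -> CompositionTable:
    """Replace zero proportions with ``epsilon`` and renormalize rows.

    The Dirichlet likelihood is undefined at the simplex boundary, so
    exact zeros must be nudged inside. ``epsilon`` must be positive and
    below ``1/K``. Already-positive tables pass through unchanged
    (renormalization is the identity), making the operation idempotent.
    """
    k = len(composition.categories)
    if not (0 < epsilon < 1.0 / k):
        raise ValueError(f"epsilon must lie in (0, 1/{k}) for {k} categories")
    props = composition.proportions.copy()
    values = props.to_numpy()
    if (values.sum(axis=1) == 0).any():
        bad = props.index[values.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero rows cannot be placed on the simplex: {bad}")
    if (values > 0).all():
        return CompositionTable(proportions=props)
    adjusted = np.where(values == 0.0, epsilon, values)
    adjusted /= adjusted.sum(axis=1, keepdims=True)
    return CompositionTable(
        proportions=pd.DataFrame(adjusted, index=props.index, columns=props.columns))


def genus_ratio(
    composition: CompositionTable,
    numerator: str,
    denominator: str,
    epsilon: float = 1e-6,
) -> pd.Series:
    """Per-sample ratio of two categories, e.g. Prevotella/Bacteroides.

    Computed as ``(p_num + eps) / (p_den + eps)`` so zero denominators
    give a finite (large) ratio rather than a division error.
    """
    for name in (numerator, denominator):
        if name not in composition.categories:
            raise ValueError(f"category {name!r} not present in table")
    num = composition.proportions[numerator] + epsilon
    den = composition.proportions[denominator] + epsilon
    ratio = num / den
    ratio.name = f"{numerator}/{denominator}"
    return ratio
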