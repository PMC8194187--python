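"""Rarefaction, alpha/beta diversity, ordination and PERMANOVA.

All the distance machinery here is implemented directly from the
definitions: Bray–Curtis dissimilarity, classical scaling (PCoA) by
eigendecomposition of the double-centred Gower matrix, and the
permutational multivariate ANOVA (pseudo-F on sequential sums of squares
of the Gower matrix, with optional within-strata permutation for
repeated-measures designs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CompositionTable, CountTable

logger = logging.getLogger(__name__)

#: The even sequencing depth used after quality control in the trial.
DEFAULT_RAREFACTION_DEPTH = 12_390


def rarefy(table: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = None) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning.
    Subsampling is multivariate hypergeometric per sample, with one child
    seed per sample spawned from ``seed`` so results do not depend on
    which other samples are present.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals
    keep = [s for s in table.samples if totals[s] >= depth]
    dropped = sorted(set(table.samples) - set(keep))
    if dropped:
        logger.warning("WARN dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    children = np.random.SeedSequence(seed).spawn(len(keep))
    columns = {}
    for sample, child in zip(keep, children):
        col = table.counts[sample].to_numpy()
        if totals[sample] == depth:
            columns[sample] = col
            continue
        rng = np.random.default_rng(child)
        columns[sample] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(columns, index=table.counts.index)
    return CountTable(counts=rare, taxonomy=table.taxonomy)


def shannon(abundances, base: float = 2.0):
    """Shannon diversity ``H = -sum p_i log_base p_i`` over positive entries.

    Accepts a single abundance vector (returns a float) or a CountTable /
    CompositionTable / DataFrame (returns a per-sample Series). Counts
    are normalised to proportions first. Base defaults to 2, the classic
    16S-pipeline convention.
    """
    if isinstance(abundances, CountTable):
        frame = abundances.counts.T  # samples as rows
    elif isinstance(abundances, CompositionTable):
        frame = abundances.proportions
    elif isinstance(abundances, pd.DataFrame):
        frame = abundances
    else:
        vec = np.asarray(abundances, dtype=float)
        return _shannon_vector(vec, base)
    return pd.Series({s: _shannon_vector(frame.loc[s].to_numpy(dtype=float), base)
                      for s in frame.index}, name="shannon")


def _shannon_vector(vec: np.ndarray, base: float) -> float:
    if (vec < 0).any():
        raise ValueError("abundances must be non-negative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an all-zero sample")
    p = vec[vec > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity ``1 - 2 sum(min(x, y)) / (sum x + sum y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(table) -> pd.DataFrame:
    """All-pairs Bray–Curtis distances for a CountTable or CompositionTable.

    Returns a symmetric, zero-diagonal DataFrame keyed by sample ID.
    """
    if isinstance(table, CountTable):
        data = table.counts.T
    elif isinstance(table, CompositionTable):
        data = table.proportions
    else:
        data = pd.DataFrame(table)
    values = data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    n = len(values)
    dm = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(values[i], values[i + 1:]).sum(axis=1)
        dm[i, i + 1:] = dm[i + 1:, i] = 1.0 - 2.0 * mins / (sums[i] + sums[i + 1:])
    return pd.DataFrame(dm, index=data.index, columns=data.index)


def _check_distance_matrix(dm: pd.DataFrame) -> np.ndarray:
    values = np.asarray(dm, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return values


def gower_center(dm: pd.DataFrame) -> np.ndarray:
    """Double-centred Gower matrix ``G = -1/2 J D^2 J`` of a distance matrix."""
    d = _check_distance_matrix(dm)
    a = -0.5 * d ** 2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


@dataclass
class PcoaResult:
    """Principal-coordinates embedding with variance bookkeeping."""

    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: pd.Series    # per retained (positive) axis

    @property
    def negative_eigenvalue_magnitude(self) -> float:
        neg = self.eigenvalues[self.eigenvalues < 0]
        return float(-neg.sum())


def pcoa(dm: pd.DataFrame, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Eigendecomposes the Gower-centred matrix; axes are ordered by
    descending eigenvalue, coordinates scaled by sqrt(eigenvalue).
    Negative eigenvalues (non-Euclidean distances) are excluded from both
    the embedding and the variance-share denominator; their total
    magnitude is logged and available on the result.
    """
    g = gower_center(dm)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10 * max(abs(eigval[0]), 1.0), 0.0)
    positive = eigval > tol
    if (eigval < -tol).any():
        logger.warning("WARN negative PCoA eigenvalues, total magnitude %.4g",
                       -eigval[eigval < -tol].sum())
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    denom = eigval[positive].sum()
    prop = eigval[positive] / denom if denom > 0 else eigval[positive]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    index = dm.index if isinstance(dm, pd.DataFrame) else pd.RangeIndex(len(g))
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=index, columns=axes),
        eigenvalues=eigval,
        proportion_explained=pd.Series(prop[:coords.shape[1]], index=axes),
    )


@dataclass
class PermanovaResult:
    """Sequential (type-I) PERMANOVA decomposition of a distance matrix."""

    table: pd.DataFrame        # term, df, sum_sq, r_squared, pseudo_f, p_value
    n_permutations: int
    total_ss: float

    def r_squared(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "r_squared"])

    def p_value(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p_value"])


def _term_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Full-dummy encoding of a main effect or ``A:B`` interaction."""
    if ":" in term:
        parts = term.split(":")
        combined = meta[parts[0]].astype(str)
        for p in parts[1:]:
            combined = combined + "\x1f" + meta[p].astype(str)
        series = combined
    else:
        series = meta[term].astype(str)
    levels = sorted(series.unique())
    if len(levels) < 2:
        raise ValueError(f"term {term!r} has a single level; nothing to test")
    return (series.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)


def permanova(
    dm: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str] | str,
    n_permutations: int = 999,
    seed: int | None = None,
    strata: str | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    Terms enter in the order given (type-I decomposition on the Gower
    matrix), so term order matters when the design is unbalanced — it is
    a user decision, not a default. P-values come from permuting sample
    labels, optionally only within the levels of ``strata`` (e.g. within
    dog for longitudinal data), and use the add-one rule
    ``(exceedances + 1) / (n_permutations + 1)``.
    """
    if isinstance(terms, str):
        terms = [t.strip() for t in terms.split(",") if t.strip()]
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    meta = metadata.copy()
    if "SampleID" in meta.columns:
        meta = meta.set_index("SampleID")
    ids = [str(s) for s in dm.index]
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    meta = meta.loc[ids]
    for term in terms:
        for col in term.split(":"):
            if col not in meta.columns:
                raise ValueError(f"metadata has no column {col!r}")

    g = gower_center(dm)
    n = len(g)
    total_ss = float(np.trace(g))

    # nested hat matrices: intercept, then +term1, +term2, ...
    design = np.ones((n, 1))
    hats = [design @ np.linalg.pinv(design)]
    ranks = [1]
    for term in terms:
        design = np.hstack([design, _term_matrix(meta, term)])
        hats.append(design @ np.linalg.pinv(design))
        ranks.append(int(np.linalg.matrix_rank(design)))
    df_terms = np.diff(ranks)
    if (df_terms == 0).any():
        aliased = [t for t, d in zip(terms, df_terms) if d == 0]
        raise ValueError(f"terms aliased with earlier terms: {aliased}")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    # increments H_j - H_{j-1} and the residual projector
    deltas = [hats[j + 1] - hats[j] for j in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]

    def decompose(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(d * gmat)) for d in deltas])
        ss_res = float(np.sum(resid_proj * gmat))
        return ss, ss_res

    ss_terms, ss_res = decompose(g)
    f_obs = (ss_terms / df_terms) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    if strata is not None:
        if strata not in meta.columns:
            raise ValueError(f"metadata has no column {strata!r}")
        strata_groups = [np.flatnonzero(meta[strata].to_numpy() == lev)
                         for lev in pd.unique(meta[strata])]
    exceed = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = np.arange(n)
        if strata is None:
            rng.shuffle(perm)
        else:
            for idx in strata_groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = decompose(gp)
        f_p = (ss_p / df_terms) / (ss_res_p / df_res)
        # ties count as exceedances; tolerance absorbs float jitter when a
        # permutation reproduces an equivalent labelling
        exceed += f_p >= f_obs - 1e-10 * np.maximum(1.0, np.abs(f_obs))
    p_values = (exceed + 1.0) / (n_permutations + 1.0)

    rows = [{"term": t, "df": int(d), "sum_sq": s,
             "r_squared": s / total_ss, "pseudo_f": f, "p_value": p}
            for t, d, s, f, p in zip(terms, df_terms, ss_terms, f_obs, p_values)]
    rows.append({"term": "Residual", "df": int(df_res), "sum_sq": ss_res,
                 "r_squared": ss_res / total_ss, "pseudo_f": np.nan,
                 "p_value": np.nan})
    table = pd.DataFrame(rows)
    return PermanovaResult(table=table, n_permutations=n_permutations,
                           total_ss=total_ss)


def distance_to_baseline(
    dm: pd.DataFrame,
    metadata: pd.DataFrame,
    baseline_period: str = "baseline",
) -> pd.DataFrame:
    """Each dog's community shift from its own baseline sample.

    For every dog with a baseline sample, returns one row per
    non-baseline period giving the distance between that period's sample
    and the dog's baseline. Dogs without a baseline are skipped with a
    warning. Output columns: ``DogID, Period, Diet, distance``.
    """
    meta = metadata.copy()
    if "SampleID" in meta.columns:
        meta = meta.set_index("SampleID")
    _check_distance_matrix(dm)
    rows = []
    for dog, block in meta.groupby("DogID", sort=True):
        base = block[block["Period"] == baseline_period]
        if base.empty:
            logger.warning("WARN dog %s has no %s sample; skipped", dog,
                           baseline_period)
            continue
        base_id = base.index[0]
        for sample_id, rec in block[block["Period"] != baseline_period].iterrows():
            if base_id not in dm.index or sample_id not in dm.index:
                continue
            rows.append({"DogID": dog, "Period": rec["Period"],
                         "Diet": rec.get("Diet", ""),
                         "distance": float(dm.loc[base_id, sample_id])})
    return pd.DataFrame(rows, columns=["DogID", "Period", "Diet", "distance"])
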