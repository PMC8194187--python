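"""Synthetic cross-over feeding-trial generator.

Emulates the post-OTU-picking stage of a two-sequence, four-period
cross-over trial in dogs: each retained dog contributes one fecal sample
per period (baseline, phase 1, washout, phase 2); dogs in sequence group
ACB receive the hydrolyzed diet (A) in phase 1 and the high-insoluble
fiber diet (B) in phase 2, group BCA the reverse, and everyone is on the
high-protein baseline diet (C) during baseline and washout.

The generative model mirrors the hierarchical Dirichlet regression the
analysis fits: each diet-by-sequence cell has a logit-scale mean
coefficient vector (reference category fixed at 0), each dog a
per-category Gaussian random intercept, the sample composition is drawn
from a Dirichlet with mean ``softmax(beta + u)`` and precision ``phi``,
and reads are multinomial at a library size drawn uniformly from the
observed depth range (12,391–165,430 by default).

One master seed expands to per-stage child seeds (random effects,
compositions, counts) via :class:`numpy.random.SeedSequence`, so each
stage is independently reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, validate_metadata
from . import io

PERIODS = ["baseline", "phase1", "washout", "phase2"]
SEQUENCES = ["ACB", "BCA"]

#: Per-sample library-size range reported for the sequenced trial.
DEFAULT_DEPTH_RANGE = (12_391, 165_430)

#: The five dominant gut phyla; used directly for small (K <= 5) simulations.
DEFAULT_PHYLA = [
    "Actinobacteria",  # reference category of the phylum-level model
    "Bacteroidetes",
    "Firmicutes",
    "Fusobacteria",
    "Proteobacteria",
]

#: Twenty common dog-gut families and their phylum, for family-level
#: simulations (reference category first).
FAMILY_PHYLUM = {
    "Bifidobacteriaceae": "Actinobacteria",  # reference category
    "Coriobacteriaceae": "Actinobacteria",
    "Bacteroidaceae": "Bacteroidetes",
    "Prevotellaceae": "Bacteroidetes",
    "Porphyromonadaceae": "Bacteroidetes",
    "Paraprevotellaceae": "Bacteroidetes",
    "Clostridiaceae": "Firmicutes",
    "Lachnospiraceae": "Firmicutes",
    "Ruminococcaceae": "Firmicutes",
    "Peptostreptococcaceae": "Firmicutes",
    "Lactobacillaceae": "Firmicutes",
    "Turicibacteraceae": "Firmicutes",
    "Erysipelotrichaceae": "Firmicutes",
    "Veillonellaceae": "Firmicutes",
    "Streptococcaceae": "Firmicutes",
    "Enterococcaceae": "Firmicutes",
    "Fusobacteriaceae": "Fusobacteria",
    "Enterobacteriaceae": "Proteobacteria",
    "Alcaligenaceae": "Proteobacteria",
    "Succinivibrionaceae": "Proteobacteria",
}
DEFAULT_FAMILIES = list(FAMILY_PHYLUM)


class DesignError(ValueError):
    """Raised for inconsistent trial-design configuration."""


@dataclass(frozen=True)
class TrialDesign:
    """Two-sequence cross-over layout with per-group exclusions."""

    n_dogs_per_group: int = 25
    exclusions_per_group: tuple[int, ...] = (2, 4)
    sequences: tuple[str, ...] = ("ACB", "BCA")
    periods: tuple[str, ...] = ("baseline", "phase1", "washout", "phase2")

    def __post_init__(self) -> None:
        if not self.periods or not self.sequences:
            raise DesignError("periods and sequences must be non-empty")
        if len(self.exclusions_per_group) != len(self.sequences):
            raise DesignError("need one exclusion count per sequence group")
        for excl in self.exclusions_per_group:
            if not (0 <= excl <= self.n_dogs_per_group):
                raise DesignError(
                    f"exclusions must satisfy 0 <= {excl} <= {self.n_dogs_per_group}"
                )

    @staticmethod
    def diet_of(period: str, sequence: str) -> str:
        """Diet label for a period within a sequence group.

        Baseline and washout are always the baseline diet C; phase 1 and
        phase 2 follow the sequence's letter order (first and last letter
        of e.g. ``"ACB"``).
        """
        if period in ("baseline", "washout"):
            return "C"
        if period == "phase1":
            return sequence[0]
        if period == "phase2":
            return sequence[-1]
        raise DesignError(f"unknown period {period!r}")

    def n_retained(self) -> int:
        return sum(self.n_dogs_per_group - e for e in self.exclusions_per_group)


def make_design(
    n_dogs_per_group: int = 25,
    exclusions_per_group: tuple[int, ...] = (2, 4),
    periods: tuple[str, ...] = ("baseline", "phase1", "washout", "phase2"),
    sequences: tuple[str, ...] = ("ACB", "BCA"),
) -> pd.DataFrame:
    """Build the sample metadata for a cross-over trial.

    Returns one record per retained dog per period, indexed by SampleID,
    with columns DogID, Group (the diet sequence), Period and Diet. Dog
    IDs are stable across periods. The printed trial (25 dogs per group,
    2 and 4 exclusions, 4 periods) yields 176 records.
    """
    design = TrialDesign(n_dogs_per_group, tuple(exclusions_per_group),
                         tuple(sequences), tuple(periods))
    records = []
    for g, (sequence, excl) in enumerate(zip(design.sequences,
                                             design.exclusions_per_group), start=1):
        for d in range(design.n_dogs_per_group - excl):
            dog = f"dog{g}_{d + 1:02d}"
            for period in design.periods:
                known = period in ("baseline", "phase1", "washout", "phase2")
                records.append({
                    "SampleID": f"{dog}.{period}",
                    "DogID": dog,
                    "Group": sequence,
                    "Period": period,
                    "Diet": TrialDesign.diet_of(period, sequence) if known else "C",
                })
    meta = pd.DataFrame.from_records(records)
    return validate_metadata(meta)


def cell_label(sequence: str, period: str) -> str:
    """Canonical diet-by-sequence cell name, e.g. ``"ACB:phase1"``.

    Baseline and washout keep separate cells (both diet C) so carry-over
    effects — baseline differing from washout under the same diet — are
    representable.
    """
    return f"{sequence}:{period}"


@dataclass
class GroundTruth:
    """Known parameters of the generative hierarchical Dirichlet model.

    ``beta`` is a (cells x categories) frame of logit-scale cell means
    with the first (reference) category fixed at 0. ``sigma_u`` gives the
    per-category random-intercept SD (reference fixed at 0); ``phi`` is
    the Dirichlet precision; ``depth_range`` the library-size interval.
    """

    categories: list[str]
    beta: pd.DataFrame
    sigma_u: pd.Series
    phi: float = 50.0
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("need at least 2 categories")
        self.beta = self.beta.reindex(columns=self.categories)
        if self.beta.isna().any().any():
            raise ValueError("beta missing entries for some categories")
        ref = self.categories[0]
        if not np.allclose(self.beta[ref], 0.0):
            raise ValueError(f"reference category {ref!r} coefficients must be 0")
        self.sigma_u = self.sigma_u.reindex(self.categories).fillna(0.0)
        if (self.sigma_u < 0).any() or not np.isfinite(self.sigma_u).all():
            raise ValueError("sigma_u must be finite and non-negative")
        if not np.isclose(self.sigma_u.iloc[0], 0.0):
            raise ValueError("reference-category sigma_u must be 0")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


def softmax(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    shifted = eta - np.max(eta, axis=axis, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=axis, keepdims=True)


def default_ground_truth(
    categories: list[str] | int | None = None,
    design: TrialDesign | None = None,
    phi: float = 50.0,
    sigma_u: float = 0.5,
    effect_scale: float = 0.8,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    seed: int | None = 0,
) -> GroundTruth:
    """Draw a plausible GroundTruth for simulation studies.

    Cell-mean coefficients are centred on a common per-category abundance
    offset (so categories differ in overall abundance, as taxa do) with
    diet/sequence/period perturbations of SD ``effect_scale`` on the
    logit scale; carry-over is emulated by giving washout cells their own
    perturbation rather than copying baseline.
    """
    if design is None:
        design = TrialDesign()
    if categories is None:
        categories = list(DEFAULT_PHYLA)
    elif isinstance(categories, int):
        k = categories
        if k <= len(DEFAULT_PHYLA):
            categories = list(DEFAULT_PHYLA)[:k]
        elif k <= len(DEFAULT_FAMILIES):
            categories = DEFAULT_FAMILIES[:k]
        else:
            extra = [f"Family{i:02d}" for i in range(1, k - len(DEFAULT_FAMILIES) + 1)]
            categories = DEFAULT_FAMILIES + extra
    rng = np.random.default_rng(seed)
    cells = [cell_label(s, p) for s in design.sequences for p in design.periods]
    k = len(categories)
    base = np.concatenate([[0.0], rng.normal(0.0, 1.0, size=k - 1)])
    beta = np.zeros((len(cells), k))
    beta[:, 1:] = base[1:] + rng.normal(0.0, effect_scale, size=(len(cells), k - 1))
    beta_frame = pd.DataFrame(beta, index=cells, columns=categories)
    sig = pd.Series(sigma_u, index=categories, dtype=float)
    sig.iloc[0] = 0.0
    return GroundTruth(categories=list(categories), beta=beta_frame, sigma_u=sig,
                       phi=phi, depth_range=depth_range)


def simulate_random_effects(
    ground_truth: GroundTruth,
    dog_ids: list[str],
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Draw per-dog, per-category Gaussian random intercepts.

    Independent N(0, sigma_u[k]^2) draws per dog and category; the
    reference category stays exactly 0. Returns a (dog x category) frame.
    """
    rng = np.random.default_rng(seed)
    k = len(ground_truth.categories)
    draws = rng.normal(0.0, 1.0, size=(len(dog_ids), k))
    draws *= ground_truth.sigma_u.to_numpy()[None, :]
    draws[:, 0] = 0.0
    return pd.DataFrame(draws, index=list(dog_ids), columns=ground_truth.categories)


def simulate_compositions(
    design_metadata: pd.DataFrame,
    ground_truth: GroundTruth,
    random_effects: pd.DataFrame,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample Dirichlet mean and drawn composition.

    ``mean = softmax(beta[cell] + u[dog])`` and the composition is drawn
    from ``Dirichlet(mean * phi)``. Returns ``(means, compositions)``,
    both (sample x category) frames with strictly positive rows summing
    to one.
    """
    if ground_truth.phi <= 0:
        raise ValueError("phi must be positive")
    meta = validate_metadata(design_metadata)
    cells = [cell_label(row.Group, row.Period) for row in meta.itertuples()]
    missing = sorted(set(cells) - set(ground_truth.beta.index))
    if missing:
        raise ValueError(f"ground truth lacks beta rows for cells: {missing}")
    eta = ground_truth.beta.loc[cells].to_numpy()
    eta = eta + random_effects.loc[meta["DogID"]].to_numpy()
    means = softmax(eta, axis=1)
    rng = np.random.default_rng(seed)
    alphas = means * ground_truth.phi
    comps = np.vstack([rng.dirichlet(alpha) for alpha in alphas])
    # Guard against zeros that standard_gamma can underflow to.
    tiny = np.finfo(float).tiny
    comps = np.clip(comps, tiny, None)
    comps /= comps.sum(axis=1, keepdims=True)
    columns = ground_truth.categories
    index = meta.index
    return (pd.DataFrame(means, index=index, columns=columns),
            pd.DataFrame(comps, index=index, columns=columns))


def simulate_counts(
    compositions: pd.DataFrame,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    seed: int | np.random.SeedSequence | None = None,
    taxonomy: pd.Series | None = None,
) -> CountTable:
    """Multinomial read counts at uniformly drawn library sizes.

    Each sample's depth is uniform on ``depth_range`` (inclusive); counts
    are multinomial(depth, composition). Returns a feature-by-sample
    CountTable whose column sums equal the drawn depths.
    """
    lo, hi = int(depth_range[0]), int(depth_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid depth range [{lo}, {hi}]")
    values = compositions.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("compositions must be non-negative")
    rng = np.random.default_rng(seed)
    depths = rng.integers(lo, hi + 1, size=values.shape[0])
    probs = values / values.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, probs)])
    frame = pd.DataFrame(counts.T, index=list(compositions.columns),
                         columns=list(compositions.index))
    if taxonomy is None:
        taxonomy = pd.Series(
            {c: _lineage_for(c) for c in compositions.columns}, dtype=object)
    return CountTable(counts=frame, taxonomy=taxonomy)


def _lineage_for(category: str) -> str:
    """Greengenes-style lineage for a simulated category label."""
    if category in DEFAULT_PHYLA:
        return f"k__Bacteria; p__{category}"
    phylum = FAMILY_PHYLUM.get(category, "Firmicutes")
    return f"k__Bacteria; p__{phylum}; f__{category}"


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    metadata: pd.DataFrame
    ground_truth: GroundTruth
    random_effects: pd.DataFrame
    means: pd.DataFrame
    compositions: pd.DataFrame
    counts: CountTable
    seed: int | None = None


def simulate_dataset(
    design: TrialDesign | None = None,
    ground_truth: GroundTruth | None = None,
    seed: int | None = 0,
) -> SimulatedDataset:
    """End-to-end simulation: design -> random effects -> compositions -> counts.

    The master ``seed`` is expanded into independent child seeds for the
    three stochastic stages, so the dataset is bit-for-bit reproducible.
    """
    if design is None:
        design = TrialDesign()
    if ground_truth is None:
        ground_truth = default_ground_truth(design=design, seed=seed)
    meta = make_design(design.n_dogs_per_group, design.exclusions_per_group,
                       design.periods, design.sequences)
    ss = np.random.SeedSequence(seed)
    seed_u, seed_comp, seed_counts = ss.spawn(3)
    dogs = list(dict.fromkeys(meta["DogID"]))
    effects = simulate_random_effects(ground_truth, dogs, seed_u)
    means, comps = simulate_compositions(meta, ground_truth, effects, seed_comp)
    counts = simulate_counts(comps, ground_truth.depth_range, seed_counts)
    return SimulatedDataset(metadata=meta, ground_truth=ground_truth,
                            random_effects=effects, means=means,
                            compositions=comps, counts=counts, seed=seed)


def write_dataset(
    counts: CountTable,
    metadata: pd.DataFrame,
    ground_truth: GroundTruth,
    directory: str | os.PathLike,
) -> dict[str, Path]:
    """Write feature table, mapping file, and ground-truth sidecar.

    The sidecar is a flat key/value text file carrying the true beta,
    sigma_u, phi and depth range — enough to rerun recovery tests against
    the written dataset.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": io.write_feature_table(counts, directory / "feature_table.tsv"),
        "mapping_file": io.write_mapping_file(metadata, directory / "mapping.tsv"),
    }
    truth: dict[str, object] = {
        "categories": ground_truth.categories,
        "phi": ground_truth.phi,
        "depth_range": list(ground_truth.depth_range),
        "sigma_u": ground_truth.sigma_u.to_numpy(),
    }
    for cell in ground_truth.beta.index:
        truth[f"beta[{cell}]"] = ground_truth.beta.loc[cell].to_numpy()
    paths["ground_truth"] = io.write_key_value(truth, directory / "ground_truth.tsv")
    return paths
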