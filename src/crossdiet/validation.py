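"""Simulation-based validation of the hierarchical Dirichlet pipeline.

The central check: simulate cross-over trials from known ground truth,
run the full modelling path (counts -> relative abundance -> zero
adjustment -> MCMC fit -> posterior prediction intervals), then draw
fresh observations from the true generative model and measure how often
they fall inside the intervals. For a calibrated procedure the pooled
coverage matches the nominal interval level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import composition as comp
from . import dirichlet
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class CoverageResult:
    """Outcome of the prediction-interval calibration experiment."""

    coverage: float                 # pooled fraction inside, all replicates
    n_indicators: int               # total fresh-draw indicators pooled
    level: float
    per_replicate: list[float] = field(default_factory=list)
    beta_bias: float = float("nan")  # mean signed error of beta, logit scale
    beta_abs_bias: float = float("nan")
    max_rhat: float = float("nan")

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.coverage

    def binomial_band(self, z: float = 1.96) -> tuple[float, float]:
        """Nominal-level band of width z binomial standard errors."""
        se = np.sqrt(self.level * (1 - self.level) / self.n_indicators)
        return self.level - z * se, self.level + z * se


def prediction_interval_coverage(
    n_replicates: int = 10,
    n_dogs_per_group: int = 10,
    k_categories: int = 5,
    phi: float = 100.0,
    sigma_u: float = 0.5,
    chains: int = 2,
    iterations: int = 2_000,
    level: float = 0.89,
    fresh_per_cell: int = 5,
    epsilon: float = 1e-6,
    seed: int | None = 0,
) -> CoverageResult:
    """Empirical coverage of posterior prediction intervals.

    For each replicate a fresh ground truth and dataset are simulated
    (two sequences, four periods, uniform library sizes in the default
    read range), the model is fitted with shortened chains, and
    ``fresh_per_cell`` new compositions per cell are drawn from the true
    Dirichlet at the population level (random intercepts zero, matching
    what the intervals describe). Coverage is pooled over replicates,
    cells, categories and fresh draws.

    Also records the signed and absolute error of the posterior-mean
    cell coefficients against the simulation truth, and the worst split
    R-hat over the core parameters, as by-products of the same fits.
    """
    master = np.random.SeedSequence(seed)
    inside = 0
    total = 0
    per_replicate: list[float] = []
    signed_errors = []
    abs_errors = []
    worst_rhat = -np.inf
    for rep, child in enumerate(master.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 4))
        design = sim.TrialDesign(n_dogs_per_group, (0, 0))
        truth = sim.default_ground_truth(
            categories=k_categories, design=design, phi=phi,
            sigma_u=sigma_u, seed=rep_seed)
        ds = sim.simulate_dataset(design, truth, seed=rep_seed)
        adjusted = comp.adjust_zeros(comp.relative_abundance(ds.counts), epsilon)
        data = dirichlet.build_design(ds.metadata, adjusted)
        spec = dirichlet.ModelSpec(chains=chains, iterations=iterations,
                                   seed=rep_seed + 1)
        draws = dirichlet.fit_mcmc(data, spec)
        core = ([f"beta[{c},{k}]" for c in draws.cells
                 for k in draws.categories[1:]] + ["phi"])
        worst_rhat = max(worst_rhat,
                         float(dirichlet.rhat_summary(draws, core).max()))
        predicted = dirichlet.predicted_intervals(draws, level=level,
                                                  seed=rep_seed + 2)
        predicted = predicted.set_index(["cell", "category"])
        est = draws.beta.reshape(-1, len(draws.cells),
                                 k_categories).mean(axis=0)
        true_beta = truth.beta.loc[draws.cells].to_numpy()
        signed_errors.append((est - true_beta)[:, 1:])
        abs_errors.append(np.abs(est - true_beta)[:, 1:].mean())
        rng = np.random.default_rng(rep_seed + 3)
        rep_inside = 0
        rep_total = 0
        for cell in draws.cells:
            mu = sim.softmax(truth.beta.loc[cell].to_numpy())
            fresh = rng.dirichlet(mu * truth.phi, size=fresh_per_cell)
            lower = predicted.loc[cell].loc[truth.categories, "lower"].to_numpy()
            upper = predicted.loc[cell].loc[truth.categories, "upper"].to_numpy()
            rep_inside += int(((fresh >= lower) & (fresh <= upper)).sum())
            rep_total += fresh.size
        inside += rep_inside
        total += rep_total
        per_replicate.append(rep_inside / rep_total)
        logger.info("replicate %d/%d: coverage %.3f", rep + 1, n_replicates,
                    rep_inside / rep_total)
    # signed error averaged over replicates first, then magnitude
    mean_signed = np.mean(np.stack(signed_errors), axis=0)
    return CoverageResult(
        coverage=inside / total,
        n_indicators=total,
        level=level,
        per_replicate=per_replicate,
        beta_bias=float(np.abs(mean_signed).mean()),
        beta_abs_bias=float(np.mean(abs_errors)),
        max_rhat=worst_rhat,
    )


def permanova_type_i_error(
    n_simulations: int = 500,
    n_samples: int = 12,
    n_taxa: int = 6,
    n_permutations: int = 99,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> float:
    """Rejection rate of PERMANOVA under an exchangeable null.

    Samples are i.i.d. compositions with no group structure; labels are
    arbitrary. A correct permutation test rejects at rate alpha.
    """
    from . import diversity as dv
    import pandas as pd

    master = np.random.SeedSequence(seed)
    rejections = 0
    for child in master.spawn(n_simulations):
        s = int(child.generate_state(1)[0] % (2**31 - 2))
        rng = np.random.default_rng(s)
        counts = rng.dirichlet(np.ones(n_taxa) * 2, size=n_samples)
        ids = [f"s{i}" for i in range(n_samples)]
        dm = dv.bray_curtis_matrix(pd.DataFrame(counts, index=ids))
        meta = pd.DataFrame(
            {"grp": ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)},
            index=ids)
        res = dv.permanova(dm, meta, ["grp"], n_permutations=n_permutations,
                           seed=s + 1)
        rejections += res.p_value("grp") <= alpha
    return rejections / n_simulations
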