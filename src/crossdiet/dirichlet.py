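"""Hierarchical Bayesian Dirichlet regression for compositional abundances.

The model: each sample's composition y (K categories, strictly inside the
simplex) is Dirichlet with mean mu and precision phi (alpha = mu * phi).
The mean follows a multivariate-logit regression with cell-means coding —
one logit-scale coefficient vector per diet-by-sequence cell, reference
category fixed at 0 — plus a per-dog, per-category Gaussian random
intercept to absorb the repeated-measures structure:

    mu_i = softmax(beta[cell_i] + u[dog_i]),   y_i ~ Dirichlet(mu_i * phi)
    beta ~ N(0, 5) elementwise,  u[d, k] ~ N(0, sd_u[k]),
    sd_u[k] ~ half-N(0, 2.5),    log phi ~ N(log 30, 1.5)

Inference is adaptive random-walk Metropolis within Gibbs blocks (one
block per cell, per dog, plus the scalar scale parameters), with the
first half of each chain used as warmup/adaptation. Convergence is
checked with the split-chain potential scale reduction statistic, and
results are summarised as fitted intervals (credible intervals for the
population mean composition) and predicted intervals (posterior
predictive for a new observation, including Dirichlet residual noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import CompositionTable, validate_metadata
from .simulate import cell_label, softmax

logger = logging.getLogger(__name__)


def dirichlet_logpdf(y, mean, phi: float):
    """Log density of Dirichlet(mean * phi) in mean-precision form.

    ``log Gamma(phi) - sum log Gamma(mu_k phi) + sum (mu_k phi - 1) log y_k``

    ``y`` and ``mean`` may be single simplex vectors or matching 2-D
    arrays (one row per observation). Boundary values (any y at 0 or 1)
    are a domain error — adjust zeros before modelling.
    """
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        raise ValueError("phi must be positive")
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("y must lie strictly inside the simplex")
    if not np.allclose(y.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("y rows must sum to 1")
    alpha = mean * phi
    out = gammaln(phi) - gammaln(alpha).sum(axis=-1) + ((alpha - 1.0) * np.log(y)).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass
class ModelSpec:
    """Configuration of the hierarchical Dirichlet regression.

    ``iterations`` is per chain, with the leading ``warmup_fraction``
    discarded (and used for proposal adaptation). ``fix_phi`` and
    ``random_intercepts=False`` are mainly for reduced toy models used in
    validation.
    """

    coefficient_prior_sd: float = 5.0
    random_sd_prior_scale: float = 2.5
    phi_log_prior_mean: float = float(np.log(30.0))
    phi_log_prior_sd: float = 1.5
    chains: int = 4
    iterations: int = 10_000
    warmup_fraction: float = 0.5
    seed: int | None = 0
    random_intercepts: bool = True
    fix_phi: float | None = None
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least 1 chain")
        if not (0.0 < self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.iterations < 4:
            raise ValueError("iterations too small")
        for name in ("coefficient_prior_sd", "random_sd_prior_scale", "phi_log_prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def warmup(self) -> int:
        return int(self.iterations * self.warmup_fraction)


@dataclass
class ModelData:
    """Design bundle produced by :func:`build_design`."""

    y: np.ndarray                 # (n, K) strictly positive compositions
    cell_index: np.ndarray        # (n,) int
    dog_index: np.ndarray         # (n,) int
    cells: list[str]
    dogs: list[str]
    categories: list[str]         # first = reference
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    @property
    def n_categories(self) -> int:
        return self.y.shape[1]


def build_design(
    metadata: pd.DataFrame,
    composition: CompositionTable,
    reference: str | None = None,
) -> ModelData:
    """Assemble model inputs: compositions, cell and dog indices.

    Cells are diet-by-sequence states labelled ``"<sequence>:<period>"``
    (baseline and washout stay distinct, so carry-over is estimable).
    The reference category is moved first; by default the first column
    of the composition table is used.
    """
    meta = validate_metadata(metadata)
    props = composition.proportions
    missing = [s for s in props.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    if not composition.is_strictly_positive():
        raise ValueError("composition must be strictly positive; run adjust_zeros first")
    categories = list(props.columns)
    if reference is not None:
        if reference not in categories:
            raise ValueError(f"reference category {reference!r} not in table")
        categories = [reference] + [c for c in categories if c != reference]
    sub = meta.loc[props.index]
    cell_of = [cell_label(row.Group, row.Period) for row in sub.itertuples()]
    cells = sorted(set(cell_of))
    dogs = sorted(set(sub["DogID"]))
    cell_index = np.array([cells.index(c) for c in cell_of])
    dog_index = np.array([dogs.index(d) for d in sub["DogID"]])
    return ModelData(
        y=props[categories].to_numpy(dtype=float),
        cell_index=cell_index,
        dog_index=dog_index,
        cells=cells,
        dogs=dogs,
        categories=categories,
        sample_ids=list(props.index),
    )


# ---------------------------------------------------------------------------
# log posterior

def _normal_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


def _halfnormal_logpdf(x, scale):
    return np.log(2.0) + _normal_logpdf(x, scale)


@dataclass
class ParamState:
    """Current sampler state; reference columns are structurally zero."""

    beta: np.ndarray              # (C, K), col 0 == 0
    u: np.ndarray                 # (D, K), col 0 == 0
    log_sd_u: np.ndarray          # (K-1,)
    log_phi: float

    def copy(self) -> "ParamState":
        return ParamState(self.beta.copy(), self.u.copy(),
                           self.log_sd_u.copy(), self.log_phi)


def _row_loglik(y_log: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    alpha = mu * phi
    return gammaln(phi) - gammaln(alpha).sum(axis=1) + ((alpha - 1.0) * y_log).sum(axis=1)


def log_posterior(state: ParamState, data: ModelData, spec: ModelSpec) -> float:
    """Joint log posterior (unnormalised) at a parameter state.

    The unconstrained parameterisation uses log phi and log sd_u; the
    sd_u Jacobian term ``+ log sd_u`` is included. With zero data rows
    this reduces to the log prior alone.
    """
    phi = spec.fix_phi if spec.fix_phi is not None else float(np.exp(state.log_phi))
    eta = state.beta[data.cell_index] + state.u[data.dog_index]
    mu = softmax(eta, axis=1)
    ll = float(_row_loglik(np.log(data.y), mu, phi).sum()) if data.n_samples else 0.0
    lp = float(_normal_logpdf(state.beta[:, 1:], spec.coefficient_prior_sd).sum())
    if spec.random_intercepts:
        sd_u = np.exp(state.log_sd_u)
        lp += float(_normal_logpdf(state.u[:, 1:], sd_u[None, :]).sum())
        lp += float((_halfnormal_logpdf(sd_u, spec.random_sd_prior_scale)
                     + state.log_sd_u).sum())
    if spec.fix_phi is None:
        lp += float(_normal_logpdf(state.log_phi - spec.phi_log_prior_mean,
                                   spec.phi_log_prior_sd))
    total = ll + lp
    if np.isnan(total) or total == np.inf:
        raise FloatingPointError("non-finite log posterior; sampler must reject")
    return total  # -inf is a valid (always-rejected) value for degenerate states


# ---------------------------------------------------------------------------
# sampler

@dataclass
class PosteriorDraws:
    """Post-warmup draws, indexed chain x iteration, for all parameters.

    ``beta`` has shape (chains, draws, cells, K) with the reference
    column identically zero; ``u`` and ``sd_u`` analogously. ``phi`` is
    (chains, draws).
    """

    beta: np.ndarray
    u: np.ndarray | None
    sd_u: np.ndarray | None
    phi: np.ndarray
    cells: list[str]
    dogs: list[str]
    categories: list[str]
    warmup: int
    seed: int | None
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def parameter_names(self) -> list[str]:
        names = [f"beta[{c},{k}]" for c in self.cells for k in self.categories[1:]]
        if self.u is not None:
            names += [f"u[{d},{k}]" for d in self.dogs for k in self.categories[1:]]
            names += [f"sd_u[{k}]" for k in self.categories[1:]]
        names.append("phi")
        return names

    def extract(self, name: str) -> np.ndarray:
        """(chains, draws) array for one named scalar parameter."""
        if name == "phi":
            return self.phi
        kind, _, inner = name.partition("[")
        keys = inner.rstrip("]").split(",")
        k = self.categories.index(keys[-1])
        if kind == "beta":
            return self.beta[:, :, self.cells.index(keys[0]), k]
        if kind == "u":
            if self.u is None:
                raise KeyError("model fitted without random intercepts")
            return self.u[:, :, self.dogs.index(keys[0]), k]
        if kind == "sd_u":
            if self.sd_u is None:
                raise KeyError("model fitted without random intercepts")
            return self.sd_u[:, :, k]
        raise KeyError(f"unknown parameter {name!r}")

    def to_long_frame(self, parameters: list[str] | None = None) -> pd.DataFrame:
        """Long-format export: columns chain, iteration, parameter, value."""
        parameters = parameters if parameters is not None else self.parameter_names()
        blocks = []
        for name in parameters:
            arr = self.extract(name)
            chains, draws = np.meshgrid(np.arange(arr.shape[0]),
                                        np.arange(arr.shape[1]), indexing="ij")
            blocks.append(pd.DataFrame({
                "chain": chains.ravel(), "iteration": draws.ravel(),
                "parameter": name, "value": arr.ravel()}))
        return pd.concat(blocks, ignore_index=True)


def _design_components(data: ModelData) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected components of the bipartite cell-dog incidence graph.

    Within a component (e.g. all cells and dogs of one diet sequence) the
    linear predictor is invariant to shifting every cell mean by a
    constant and the member dogs' intercepts by its negative; the sampler
    exploits this ridge with a dedicated recentering move.
    """
    n_cells, n_dogs = len(data.cells), len(data.dogs)
    parent = list(range(n_cells + n_dogs))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for c, d in zip(data.cell_index, data.dog_index):
        rc, rd = find(int(c)), find(n_cells + int(d))
        if rc != rd:
            parent[rd] = rc
    groups: dict[int, tuple[list[int], list[int]]] = {}
    for c in range(n_cells):
        groups.setdefault(find(c), ([], []))[0].append(c)
    for d in range(n_dogs):
        groups.setdefault(find(n_cells + d), ([], []))[1].append(d)
    return [(np.array(cs), np.array(ds)) for cs, ds in groups.values() if cs and ds]


class _AdaptiveScale:
    """Robbins-Monro style proposal-scale adaptation during warmup."""

    def __init__(self, scale: float, target: float, every: int = 25) -> None:
        self.scale = scale
        self.target = target
        self.every = every
        self.accepted = 0
        self.proposed = 0
        self.rounds = 0
        self.total_accepted = 0
        self.total_proposed = 0

    def record(self, accepted: bool, adapting: bool) -> None:
        self.proposed += 1
        self.accepted += int(accepted)
        if not adapting:
            self.total_proposed += 1
            self.total_accepted += int(accepted)
            return
        if self.proposed >= self.every:
            self.rounds += 1
            rate = self.accepted / self.proposed
            self.scale *= float(np.exp((rate - self.target) / np.sqrt(self.rounds)))
            self.scale = float(np.clip(self.scale, 1e-4, 50.0))
            self.accepted = self.proposed = 0

    @property
    def post_warmup_rate(self) -> float:
        return self.total_accepted / max(self.total_proposed, 1)


def _initial_state(data: ModelData, spec: ModelSpec, rng: np.random.Generator,
                   dispersion: float) -> ParamState:
    k = data.n_categories
    n_cells, n_dogs = len(data.cells), len(data.dogs)
    beta = np.zeros((n_cells, k))
    if data.n_samples:
        global_mean = data.y.mean(axis=0)
        for c in range(n_cells):
            rows = data.y[data.cell_index == c]
            m = rows.mean(axis=0) if len(rows) else global_mean
            m = 0.9 * m + 0.1 * global_mean  # shrink away from extreme logits
            beta[c] = np.log(m) - np.log(m[0])
    beta[:, 1:] += rng.normal(0.0, dispersion, size=(n_cells, k - 1))
    u = np.zeros((n_dogs, k))
    log_sd_u = np.log(0.3) + rng.normal(0.0, dispersion, size=k - 1)
    if data.n_samples:
        var = data.y.var(axis=0).mean()
        mu = data.y.mean(axis=0)
        phi0 = float(np.clip((mu * (1 - mu)).mean() / max(var, 1e-8) - 1.0, 1.0, 1e4))
    else:
        phi0 = 30.0
    log_phi = float(np.log(phi0) + rng.normal(0.0, dispersion))
    return ParamState(beta, u, log_sd_u, log_phi)


def fit_mcmc(data: ModelData, spec: ModelSpec | None = None) -> PosteriorDraws:
    """Sample the posterior with blockwise adaptive random-walk Metropolis.

    Each chain starts from a dispersed initialisation around empirical
    cell means; proposal scales adapt toward the target acceptance rate
    during warmup and are frozen afterwards. Draws are reproducible given
    ``spec.seed``.
    """
    spec = spec or ModelSpec()
    k = data.n_categories
    warmup = spec.warmup
    kept = spec.iterations - warmup
    chain_seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)

    y_log = np.log(data.y)
    n_cells, n_dogs = len(data.cells), len(data.dogs)
    cell_rows = [np.flatnonzero(data.cell_index == c) for c in range(n_cells)]
    dog_rows = [np.flatnonzero(data.dog_index == d) for d in range(n_dogs)]
    components = _design_components(data)

    beta_out = np.empty((spec.chains, kept, n_cells, k))
    u_out = np.empty((spec.chains, kept, n_dogs, k)) if spec.random_intercepts else None
    sd_out = np.empty((spec.chains, kept, k)) if spec.random_intercepts else None
    phi_out = np.empty((spec.chains, kept))
    acceptance: dict[str, float] = {}

    for chain, chain_seed in enumerate(chain_seeds):
        rng = np.random.default_rng(chain_seed)
        state = _initial_state(data, spec, rng, dispersion=0.1 * (1 + chain % 4))
        phi = spec.fix_phi if spec.fix_phi is not None else float(np.exp(state.log_phi))
        eta = state.beta[data.cell_index] + state.u[data.dog_index]
        mu = softmax(eta, axis=1)
        row_ll = _row_loglik(y_log, mu, phi)
        if not np.isfinite(row_ll.sum()):
            raise FloatingPointError("non-finite initial likelihood")

        scales = {
            **{f"beta{c}": _AdaptiveScale(0.1, spec.target_acceptance) for c in range(n_cells)},
            **{f"u{d}": _AdaptiveScale(0.1, spec.target_acceptance) for d in range(n_dogs)},
            "sd_u": _AdaptiveScale(0.2, spec.target_acceptance),
            "phi": _AdaptiveScale(0.2, spec.target_acceptance),
        }
        if spec.random_intercepts:
            scales.update({f"recenter{g}": _AdaptiveScale(0.1, spec.target_acceptance)
                           for g in range(len(components))})

        for it in range(spec.iterations):
            adapting = it < warmup
            # --- beta blocks -------------------------------------------------
            for c in range(n_cells):
                sc = scales[f"beta{c}"]
                rows = cell_rows[c]
                prop = state.beta[c].copy()
                prop[1:] += rng.normal(0.0, sc.scale, size=k - 1)
                new_mu = softmax(prop[None, :] + state.u[data.dog_index[rows]], axis=1)
                new_ll = _row_loglik(y_log[rows], new_mu, phi)
                d_prior = (_normal_logpdf(prop[1:], spec.coefficient_prior_sd).sum()
                           - _normal_logpdf(state.beta[c, 1:], spec.coefficient_prior_sd).sum())
                delta = new_ll.sum() - row_ll[rows].sum() + d_prior
                accept = np.isfinite(delta) and np.log(rng.uniform()) < delta
                if accept:
                    state.beta[c] = prop
                    mu[rows] = new_mu
                    row_ll[rows] = new_ll
                sc.record(accept, adapting)
            # --- random-intercept blocks ------------------------------------
            if spec.random_intercepts:
                sd_u = np.exp(state.log_sd_u)
                for d in range(n_dogs):
                    sc = scales[f"u{d}"]
                    rows = dog_rows[d]
                    prop = state.u[d].copy()
                    prop[1:] += rng.normal(0.0, sc.scale, size=k - 1)
                    new_mu = softmax(state.beta[data.cell_index[rows]] + prop[None, :], axis=1)
                    new_ll = _row_loglik(y_log[rows], new_mu, phi)
                    d_prior = (_normal_logpdf(prop[1:], sd_u).sum()
                               - _normal_logpdf(state.u[d, 1:], sd_u).sum())
                    delta = new_ll.sum() - row_ll[rows].sum() + d_prior
                    accept = np.isfinite(delta) and np.log(rng.uniform()) < delta
                    if accept:
                        state.u[d] = prop
                        mu[rows] = new_mu
                        row_ll[rows] = new_ll
                    sc.record(accept, adapting)
                # --- sd_u block (priors only; likelihood untouched) ----------
                sc = scales["sd_u"]
                prop_log_sd = state.log_sd_u + rng.normal(0.0, sc.scale, size=k - 1)

                def sd_target(log_sd: np.ndarray) -> float:
                    sd = np.exp(log_sd)
                    return float(_normal_logpdf(state.u[:, 1:], sd[None, :]).sum()
                                 + (_halfnormal_logpdf(sd, spec.random_sd_prior_scale)
                                    + log_sd).sum())

                delta = sd_target(prop_log_sd) - sd_target(state.log_sd_u)
                accept = np.isfinite(delta) and np.log(rng.uniform()) < delta
                if accept:
                    state.log_sd_u = prop_log_sd
                sc.record(accept, adapting)
                # --- recentering moves along the beta/u ridge ----------------
                # shifting all cell means of a component and subtracting the
                # shift from its dogs' intercepts leaves eta (and the
                # likelihood) unchanged; only the priors vote.
                sd_u = np.exp(state.log_sd_u)
                for g, (cs, ds) in enumerate(components):
                    sc = scales[f"recenter{g}"]
                    shift = rng.normal(0.0, sc.scale, size=k - 1)
                    new_beta = state.beta[np.ix_(cs, np.arange(1, k))] + shift
                    new_u = state.u[np.ix_(ds, np.arange(1, k))] - shift
                    delta = (
                        _normal_logpdf(new_beta, spec.coefficient_prior_sd).sum()
                        - _normal_logpdf(state.beta[np.ix_(cs, np.arange(1, k))],
                                         spec.coefficient_prior_sd).sum()
                        + _normal_logpdf(new_u, sd_u).sum()
                        - _normal_logpdf(state.u[np.ix_(ds, np.arange(1, k))],
                                         sd_u).sum())
                    accept = np.isfinite(delta) and np.log(rng.uniform()) < delta
                    if accept:
                        state.beta[np.ix_(cs, np.arange(1, k))] = new_beta
                        state.u[np.ix_(ds, np.arange(1, k))] = new_u
                    sc.record(accept, adapting)
            # --- phi ---------------------------------------------------------
            if spec.fix_phi is None:
                sc = scales["phi"]
                prop_log_phi = state.log_phi + rng.normal(0.0, sc.scale)
                new_phi = float(np.exp(prop_log_phi))
                new_ll = _row_loglik(y_log, mu, new_phi)
                d_prior = (_normal_logpdf(prop_log_phi - spec.phi_log_prior_mean,
                                          spec.phi_log_prior_sd)
                           - _normal_logpdf(state.log_phi - spec.phi_log_prior_mean,
                                            spec.phi_log_prior_sd))
                delta = new_ll.sum() - row_ll.sum() + d_prior
                accept = np.isfinite(delta) and np.log(rng.uniform()) < delta
                if accept:
                    state.log_phi = prop_log_phi
                    phi = new_phi
                    row_ll = new_ll
                sc.record(accept, adapting)

            if it >= warmup:
                j = it - warmup
                beta_out[chain, j] = state.beta
                if spec.random_intercepts:
                    u_out[chain, j] = state.u
                    sd_out[chain, j, 0] = 0.0
                    sd_out[chain, j, 1:] = np.exp(state.log_sd_u)
                phi_out[chain, j] = phi

        for name, sc in scales.items():
            acceptance[f"chain{chain}:{name}"] = sc.post_warmup_rate

    rates = np.array(list(acceptance.values()))
    logger.info("post-warmup acceptance: mean %.2f, min %.2f, max %.2f",
                rates.mean(), rates.min(), rates.max())
    return PosteriorDraws(
        beta=beta_out, u=u_out, sd_u=sd_out, phi=phi_out,
        cells=data.cells, dogs=data.dogs, categories=data.categories,
        warmup=warmup, seed=spec.seed, acceptance=acceptance,
    )


# ---------------------------------------------------------------------------
# diagnostics

def rhat(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction statistic.

    Each chain is split in half; the statistic compares between- and
    within-half-chain variances. Values near 1 indicate mixing. Requires
    at least 2 chains and 4 post-warmup draws per chain. Zero total
    variance yields NaN with a warning rather than an error.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        arr = draws.extract(parameter)
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    m, n = arr.shape
    if m < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n // 2
    halves = np.vstack([arr[:, :half], arr[:, half:2 * half]])
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        logger.warning("WARN zero within-chain variance; R-hat undefined")
        return float("nan")
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def rhat_summary(draws: PosteriorDraws, parameters: list[str] | None = None) -> pd.Series:
    """R-hat for every (or the given) parameters, as a Series."""
    names = parameters if parameters is not None else draws.parameter_names()
    if draws.sd_u is None and parameters is None:
        names = [n for n in names if not n.startswith(("u[", "sd_u["))]
    if np.ptp(draws.phi) == 0 and parameters is None:  # fixed phi
        names = [n for n in names if n != "phi"]
    return pd.Series({name: rhat(draws, name) for name in names}, name="rhat")


# ---------------------------------------------------------------------------
# interval summaries

def _flat_beta(draws: PosteriorDraws) -> np.ndarray:
    """(total draws, cells, K) pooled over chains."""
    s = draws.beta.shape
    return draws.beta.reshape(s[0] * s[1], s[2], s[3])


def fitted_intervals(draws: PosteriorDraws, level: float = 0.89) -> pd.DataFrame:
    """Credible intervals for the population mean composition per cell.

    Random effects are set to zero: the summarised quantity is
    ``softmax(beta_cell)``, the population-level mean. Points are
    posterior means; bounds equal-tailed quantiles. Per cell, the point
    estimates sum to 1 across categories.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    beta = _flat_beta(draws)
    mu = softmax(beta, axis=2)           # (draws, cells, K)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for c, cell in enumerate(draws.cells):
        for k, cat in enumerate(draws.categories):
            vals = mu[:, c, k]
            rows.append({"cell": cell, "category": cat, "kind": "fitted",
                         "level": level, "point": float(vals.mean()),
                         "lower": float(np.quantile(vals, lo)),
                         "upper": float(np.quantile(vals, hi))})
    return pd.DataFrame(rows)


def predicted_intervals(
    draws: PosteriorDraws,
    level: float = 0.89,
    include_random_effects: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Posterior predictive intervals for a new observation per cell.

    For each posterior draw a fresh composition is drawn from
    ``Dirichlet(softmax(beta_cell) * phi)``, so the intervals include the
    Dirichlet residual variation on top of posterior uncertainty; points
    remain the posterior population mean, matching the fitted table.
    Inter-subject variation is excluded by default;
    ``include_random_effects=True`` additionally draws a new dog's random
    intercept from N(0, sd_u) before the softmax.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if include_random_effects and draws.sd_u is None:
        raise ValueError("fit has no random-effect draws")
    beta = _flat_beta(draws)             # (S, C, K)
    phi = draws.phi.reshape(-1)          # (S,)
    s, c, k = beta.shape
    rng = np.random.default_rng(draws.seed if seed is None else seed)
    eta = beta
    if include_random_effects:
        sd = draws.sd_u.reshape(-1, k)   # (S, K)
        eta = beta + (rng.normal(size=(s, c, k)) * sd[:, None, :])
        eta[..., 0] = 0.0
    mu = softmax(eta, axis=2)
    alpha = mu * phi[:, None, None]
    # Dirichlet draws via normalised gammas, vectorised over draws and cells
    gam = rng.standard_gamma(alpha)
    gam = np.clip(gam, np.finfo(float).tiny, None)
    pred = gam / gam.sum(axis=2, keepdims=True)
    mu_pop = softmax(beta, axis=2)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for ci, cell in enumerate(draws.cells):
        for ki, cat in enumerate(draws.categories):
            vals = pred[:, ci, ki]
            rows.append({"cell": cell, "category": cat, "kind": "predicted",
                         "level": level, "point": float(mu_pop[:, ci, ki].mean()),
                         "lower": float(np.quantile(vals, lo)),
                         "upper": float(np.quantile(vals, hi))})
    return pd.DataFrame(rows)
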