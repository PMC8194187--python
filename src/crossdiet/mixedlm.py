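"""Linear mixed model with a single subject-level random intercept.

Built for the alpha-diversity analysis of a cross-over trial: Shannon
index (or any per-sample response, e.g. log-transformed predicted
pathway abundances) regressed on diet, sequence and their interaction as
fixed effects, with a per-dog random intercept absorbing the
repeated-measures correlation. Estimation is REML with the variance
ratio gamma = sigma2_subject / sigma2_residual profiled out, which makes
the optimisation one-dimensional and robust (Brent search on log gamma,
with the gamma = 0 boundary checked explicitly).

Model informativeness is summarised by the marginal and conditional
coefficients of determination: the variance explained by the fixed
effects alone, and by fixed plus random effects, as fractions of the
total (fixed + subject + residual) variance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    """Raised when the fixed-effect design is not full rank."""


def _encode_term(meta: pd.DataFrame, term: str, levels: dict[str, list[str]]):
    """Treatment-coded columns for a main effect or ``A:B`` interaction."""
    factors = term.split(":")
    for f in factors:
        if f not in meta.columns:
            raise ValueError(f"metadata has no column {f!r}")
    blocks = []
    for f in factors:
        ref = levels[f][0]
        cols = {f"{f}[{lev}]": (meta[f].astype(str) == lev).astype(float)
                for lev in levels[f][1:]}
        blocks.append(pd.DataFrame(cols, index=meta.index))
    out = blocks[0]
    for nxt in blocks[1:]:
        combined = {}
        for a in out.columns:
            for b in nxt.columns:
                combined[f"{a}:{b}"] = out[a] * nxt[b]
        out = pd.DataFrame(combined, index=meta.index)
    return out


def build_fixed_design(
    metadata: pd.DataFrame,
    fixed_terms: list[str],
    reference: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept + treatment-coded design matrix for the fixed effects.

    Factor levels are sorted alphabetically with the first level as the
    reference (overridable per factor via ``reference``).
    """
    factors = sorted({f for t in fixed_terms for f in t.split(":")})
    levels: dict[str, list[str]] = {}
    for f in factors:
        if f not in metadata.columns:
            raise ValueError(f"metadata has no column {f!r}")
        levs = sorted(metadata[f].astype(str).unique())
        if reference and f in reference:
            if reference[f] not in levs:
                raise ValueError(f"reference {reference[f]!r} not a level of {f!r}")
            levs = [reference[f]] + [l for l in levs if l != reference[f]]
        levels[f] = levs
    design = pd.DataFrame({"Intercept": np.ones(len(metadata))}, index=metadata.index)
    for term in fixed_terms:
        design = pd.concat([design, _encode_term(metadata, term, levels)], axis=1)
    return design, levels


@dataclass
class LmmFit:
    """REML fit of a random-intercept linear mixed model."""

    coefficients: pd.Series          # fixed effects, named by design column
    cov_coefficients: pd.DataFrame   # covariance of the fixed effects
    sigma2_subject: float
    sigma2_residual: float
    reml_loglik: float
    converged: bool
    design: pd.DataFrame             # fixed-effect design actually used
    levels: dict[str, list[str]]     # factor -> ordered levels (ref first)
    fixed_terms: list[str]
    subjects: pd.Series              # per-observation subject labels
    response: pd.Series

    @property
    def n_observations(self) -> int:
        return len(self.response)

    @property
    def fitted_fixed(self) -> pd.Series:
        """Fixed-effect predictions X beta for the estimation data."""
        return pd.Series(self.design.to_numpy() @ self.coefficients.to_numpy(),
                         index=self.design.index, name="fitted")

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_coefficients))
        z = self.coefficients.to_numpy() / np.where(se > 0, se, np.nan)
        return pd.DataFrame({
            "estimate": self.coefficients, "se": se, "z": z,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        })


def _reml_neg2ll(gamma: float, y: np.ndarray, x: np.ndarray,
                 groups: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled -2 REML log-likelihood at variance ratio gamma.

    Exploits the block structure of V0 = I + gamma Z Z' (Z = subject
    indicators) through Woodbury: V0^-1 = I - gamma/(1+gamma*n_g) per
    group block. Returns (-2LL, beta, cov_beta_unscaled, sigma2_resid).
    """
    n, p = x.shape
    unique, counts = np.unique(groups, return_counts=True)
    # V0^-1 applied to a matrix, block by block
    def vinv(mat: np.ndarray) -> np.ndarray:
        out = mat.copy()
        for g, ng in zip(unique, counts):
            idx = groups == g
            shrink = gamma / (1.0 + gamma * ng)
            out[idx] -= shrink * mat[idx].sum(axis=0)
        return out

    xtvx = x.T @ vinv(x)
    xtvy = x.T @ vinv(y.reshape(-1, 1)).ravel()
    beta = np.linalg.solve(xtvx, xtvy)
    resid = y - x @ beta
    q = float(resid @ vinv(resid.reshape(-1, 1)).ravel())
    sigma2 = q / (n - p)
    logdet_v0 = float(np.sum(np.log1p(gamma * counts)))
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf, beta, xtvx, sigma2
    neg2 = ((n - p) * np.log(sigma2) + logdet_v0 + logdet_xtvx
            + (n - p) + (n - p) * np.log(2 * np.pi))
    return neg2, beta, xtvx, sigma2


def fit_reml(
    response: pd.Series,
    metadata: pd.DataFrame,
    fixed_terms: list[str] | str = ("Diet", "Group", "Diet:Group"),
    subject: str = "DogID",
    reference: dict[str, str] | None = None,
) -> LmmFit:
    """Fit the random-intercept LMM by REML.

    ``response`` is aligned to ``metadata`` (indexed by sample ID).
    Raises on rank-deficient designs (listing aliased columns), fewer
    than two subjects, or designs with one observation per subject,
    where the two variance components are not separately identifiable.
    """
    if isinstance(fixed_terms, str):
        fixed_terms = [t.strip() for t in fixed_terms.split(",") if t.strip()]
    fixed_terms = list(fixed_terms)
    meta = metadata.copy()
    if "SampleID" in meta.columns:
        meta = meta.set_index("SampleID")
    common = [s for s in response.index if s in meta.index]
    if len(common) < len(response):
        raise ValueError("response contains samples missing from metadata")
    meta = meta.loc[response.index]
    if subject not in meta.columns:
        raise ValueError(f"metadata has no column {subject!r}")
    subjects = meta[subject].astype(str)
    if subjects.nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if subjects.value_counts().max() == 1:
        raise ValueError(
            "one observation per subject: sigma2_subject and sigma2_residual "
            "are not separately identifiable")
    design, levels = build_fixed_design(meta, fixed_terms, reference)
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        aliased = [design.columns[j] for j in range(x.shape[1])
                   if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise RankDeficientError(f"design is rank deficient; aliased: {aliased}")
    y = response.to_numpy(dtype=float)
    codes = pd.factorize(subjects)[0]

    if np.ptp(y) == 0:  # constant response: both components zero
        beta = np.zeros(x.shape[1])
        beta[0] = y[0]
        coef = pd.Series(beta, index=design.columns)
        cov = pd.DataFrame(np.zeros((len(beta), len(beta))),
                           index=design.columns, columns=design.columns)
        return LmmFit(coef, cov, 0.0, 0.0, np.nan, True, design, levels,
                      fixed_terms, subjects, response)

    def objective(theta: float) -> float:
        return _reml_neg2ll(float(np.exp(theta)), y, x, codes)[0]

    res = optimize.minimize_scalar(objective, bounds=(-18.0, 18.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    best_gamma = float(np.exp(res.x))
    neg2_best = res.fun
    neg2_zero = _reml_neg2ll(0.0, y, x, codes)[0]
    if neg2_zero <= neg2_best + 1e-9 or best_gamma < 1e-8:
        best_gamma = 0.0
        neg2_best = neg2_zero
    neg2, beta, xtvx, sigma2 = _reml_neg2ll(best_gamma, y, x, codes)
    cov = np.linalg.inv(xtvx) * sigma2
    coef = pd.Series(beta, index=design.columns, name="estimate")
    return LmmFit(
        coefficients=coef,
        cov_coefficients=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        sigma2_subject=best_gamma * sigma2,
        sigma2_residual=sigma2,
        reml_loglik=-0.5 * neg2,
        converged=bool(res.success),
        design=design, levels=levels, fixed_terms=fixed_terms,
        subjects=subjects, response=response,
    )


def r2_nakagawa(fit: LmmFit) -> tuple[float, float]:
    """Marginal and conditional coefficients of determination.

    marginal = var_fixed / (var_fixed + sigma2_subject + sigma2_residual);
    conditional adds sigma2_subject to the numerator. ``var_fixed`` is
    the sample variance of the fixed-effect predictions.
    """
    var_f = float(np.var(fit.fitted_fixed.to_numpy(), ddof=1))
    total = var_f + fit.sigma2_subject + fit.sigma2_residual
    if total <= 0:
        raise ValueError("zero total variance; R2 undefined")
    return var_f / total, (var_f + fit.sigma2_subject) / total


def _reference_grid(fit: LmmFit) -> pd.DataFrame:
    factors = sorted({f for t in fit.fixed_terms for f in t.split(":")})
    combos = list(itertools.product(*[fit.levels[f] for f in factors]))
    return pd.DataFrame(combos, columns=factors)


def _grid_design(fit: LmmFit, grid: pd.DataFrame) -> np.ndarray:
    design = pd.DataFrame({"Intercept": np.ones(len(grid))}, index=grid.index)
    for term in fit.fixed_terms:
        design = pd.concat([design, _encode_term(grid, term, fit.levels)], axis=1)
    return design[fit.design.columns].to_numpy(dtype=float)


def marginal_means(fit: LmmFit, term: str, level: float = 0.95) -> pd.DataFrame:
    """Adjusted (estimated marginal) means of one factor with Wald CIs.

    Predictions on the full factor grid are averaged with equal weights
    over the levels of the other factors; intervals use the z quantile
    at ``level`` (1.959964 for 95%) and the REML fixed-effect covariance.
    """
    if term not in {f for t in fit.fixed_terms for f in t.split(":")}:
        raise ValueError(f"unknown term {term!r}")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    grid = _reference_grid(fit)
    gx = _grid_design(fit, grid)
    z = stats.norm.ppf(0.5 + level / 2)
    cov = fit.cov_coefficients.to_numpy()
    beta = fit.coefficients.to_numpy()
    rows = []
    for lev in fit.levels[term]:
        mask = (grid[term] == lev).to_numpy()
        weights = mask / mask.sum()
        contrast = weights @ gx
        est = float(contrast @ beta)
        se = float(np.sqrt(contrast @ cov @ contrast))
        rows.append({"level": lev, "mean": est, "se": se,
                     "lower": est - z * se, "upper": est + z * se})
    return pd.DataFrame(rows)


def pairwise_contrasts(
    fit: LmmFit,
    term: str,
    adjustment: str = "tukey",
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise differences of marginal means with multiplicity control.

    ``tukey`` uses the single-step max-|z| adjustment under the joint
    normal distribution of the contrast estimates (evaluated by a large
    seeded Monte-Carlo sample, robust to the singular contrast
    covariance); ``bonferroni`` multiplies raw p-values by the number of
    contrasts; ``none`` reports raw p-values.
    """
    levels_ = fit.levels.get(term)
    if levels_ is None:
        raise ValueError(f"unknown term {term!r}")
    if len(levels_) < 2:
        raise ValueError(f"term {term!r} has fewer than 2 levels")
    grid = _reference_grid(fit)
    gx = _grid_design(fit, grid)
    cov = fit.cov_coefficients.to_numpy()
    beta = fit.coefficients.to_numpy()
    contrast_rows = []
    pairs = list(itertools.combinations(levels_, 2))
    for a, b in pairs:
        wa = (grid[term] == a).to_numpy().astype(float)
        wb = (grid[term] == b).to_numpy().astype(float)
        contrast_rows.append((wa / wa.sum() - wb / wb.sum()) @ gx)
    cmat = np.vstack(contrast_rows)
    est = cmat @ beta
    vcov = cmat @ cov @ cmat.T
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    zstat = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    raw = 2 * stats.norm.sf(np.abs(zstat))
    if adjustment == "none":
        adj = raw
    elif adjustment == "bonferroni":
        adj = np.minimum(1.0, raw * len(pairs))
    elif adjustment == "tukey":
        denom = np.where(se > 0, se, 1.0)
        corr = vcov / np.outer(denom, denom)
        rng = np.random.default_rng(seed)
        eigval, eigvec = np.linalg.eigh(corr)
        root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
        draws = rng.standard_normal((200_000, corr.shape[0])) @ root.T
        maxabs = np.abs(draws).max(axis=1)
        adj = np.array([(np.sum(maxabs >= abs(z0)) + 1) / (len(maxabs) + 1)
                        for z0 in zstat])
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return pd.DataFrame({
        "contrast": [f"{a} - {b}" for a, b in pairs],
        "estimate": est, "se": se, "z": zstat,
        "p_raw": raw, "p_adjusted": adj,
    })


def log_response(table: pd.DataFrame | pd.Series, offset: float = 0.0):
    """Natural-log transform ``log(value + offset)`` of a response table.

    Used for predicted-pathway abundances before the mixed model; the
    offset is recorded in the result's attrs.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    values = np.asarray(table, dtype=float)
    if ((values + offset) <= 0).any():
        raise ValueError("non-positive values; use a positive offset")
    out = np.log(values + offset)
    if isinstance(table, pd.Series):
        res = pd.Series(out, index=table.index, name=table.name)
    elif isinstance(table, pd.DataFrame):
        res = pd.DataFrame(out, index=table.index, columns=table.columns)
    else:
        return out
    res.attrs["log_offset"] = offset
    return res
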