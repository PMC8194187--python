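# Methods

`crossdiet` implements the statistical pipeline for a two-sequence,
four-period cross-over feeding trial read out by 16S amplicon profiling.
This note records the models, the defaults and why, the numerical
choices, and what the simulation-based tests do and do not demonstrate.

## Trial design and the synthetic-data generator

The design is two groups of dogs on the diet sequences ACB and BCA
(A = hydrolyzed, B = high-insoluble fiber, C = high-protein baseline
diet), sampled at four points: baseline, end of phase 1, end of a
washout on diet C, and end of phase 2. Defaults follow the trial the
package models: 25 dogs per group with 2 and 4 exclusions, hence
(23 + 21) x 4 = 176 samples.

The generator works at the count-table level (it does not simulate
reads, chimeras or OTU picking) and mirrors the hierarchical model the
package fits, so every simulated dataset has known ground truth:

1. each diet-by-sequence **cell** (8 cells in the default design:
   4 periods x 2 sequences) has a logit-scale coefficient vector
   `beta[cell, :]` with the reference category fixed at 0. Baseline and
   washout keep separate cells even though both are diet C — carry-over
   (baseline != washout) is representable, matching the repeated finding
   that communities do not revert after washout;
2. each dog has an independent per-category Gaussian intercept
   `u[dog, k] ~ N(0, sigma_u[k])` (no cross-category covariance, matching
   the model actually fitted);
3. the sample mean is `mu = softmax(beta + u)` and the composition is
   drawn from `Dirichlet(mu * phi)`;
4. counts are multinomial at a library size drawn uniformly from
   12,391–165,430 reads — the printed per-sample range. Only the range
   (with median and mean) is reported for the real data, so the uniform
   is an explicit stand-in, not an inference about the true depth
   distribution.

Default generator parameters where the study reports none: Dirichlet
precision `phi = 50` (dispersion comparable to the wide per-diet
abundance ranges summarised for the real data), random-intercept SD
`sigma_u = 0.5` on the logit scale (dogs differ visibly but do not swap
rank order of taxa), cell-effect SD 0.8 around per-category abundance
offsets drawn from N(0, 1). The 20-family inventory uses common dog-gut
families with their phylum lineages so both family- and phylum-level
aggregation paths are exercised.

One master seed expands through `numpy.random.SeedSequence` into child
seeds per stage (random effects, compositions, counts), so a dataset is
bit-for-bit reproducible and stages can be replayed independently.

**What the simulator does not emulate:** sequencing error, chimeras,
compositional zero-inflation beyond what the Dirichlet induces,
taxonomic misassignment, or within-period temporal drift. Passing
recovery tests on these simulations shows the estimators are correct
for the assumed generative model; it does not validate the model against
real sequencing artefacts.

## Compositional preparation

Counts are aggregated by Greengenes lineage label at phylum/family/genus
rank (features lacking the rank pooled as `Unassigned`), converted to
proportions, and optionally reduced to the K most abundant categories
plus an `OTHER` residual so rows still sum to one. Ranking is by
across-sample mean proportion (not prevalence), ties broken
alphabetically for determinism. Summaries are reported as median with
range, the midpoint convention for even group sizes.

Zeros are disallowed by the Dirichlet likelihood. `adjust_zeros`
replaces exact zeros with `epsilon` (default 1e-6, far below any
plausible detection limit at ~12k reads) and renormalises the row. The
operation is idempotent on already-positive tables. Whether the original
analysis added its adjustment before or after normalisation is not
recorded anywhere; this implementation's choice is explicit rather than
a reconstruction.

## Diversity

- **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric) to the even depth, default 12,390;
  shallower samples are dropped with a `WARN`-prefixed log line. One
  child seed per sample keeps a sample's rarefied counts independent of
  which other samples are present.
- **Shannon index** uses log base 2 by default (the classic QIIME
  convention; the natural log is an option).
- **Bray–Curtis** is computed from the definition
  `1 - 2*sum(min)/sum(both)`, by default on rarefied counts.
- **PCoA** is classical scaling: eigendecomposition of the
  double-centred Gower matrix. Negative eigenvalues (Bray–Curtis is not
  Euclidean) are excluded from both the embedding and the
  variance-share denominator; their total magnitude is logged. No
  Cailliez correction.
- **PERMANOVA** partitions `tr(G)` by sequential (type-I) projections of
  nested design matrices, so term order is a user decision — the
  original report does not print its term order, and order matters in
  unbalanced designs. P-values permute sample labels freely by default
  (the conventional choice) with an optional `strata` argument (e.g.
  within dog) for the repeated-measures-respecting alternative, and use
  the add-one rule, so they are never 0. Tied pseudo-F values under
  equivalent relabelings are counted as exceedances with a 1e-10
  relative tolerance to absorb float jitter.

## The hierarchical Dirichlet regression

The response is the strictly-positive composition (after top-K/OTHER
and zero adjustment); the likelihood is Dirichlet in mean–precision
form, `alpha = mu * phi` with a single precision shared across cells.
The mean uses a multivariate-logit (softmax) link with cell-means
coding: one coefficient vector per diet-by-sequence cell per
non-reference category, plus per-dog per-category random intercepts.
Reference levels mirror the original choices (Actinobacteria at phylum
level, Bifidobacteriaceae at family level) via the `reference` argument.

Priors: `N(0, 5)` on free coefficients (as reported); the remaining
priors are not printed anywhere and are explicit configuration here —
`sd_u ~ half-N(0, 2.5)` and `log phi ~ N(log 30, 1.5)`, both weakly
informative on the scales microbiome compositions occupy.

**Sampler.** Adaptive random-walk Metropolis within Gibbs blocks: one
block per cell (the K-1 free coefficients jointly), one per dog, a joint
block for `log sd_u`, and scalar `log phi`. Proposal scales adapt toward
~0.3 acceptance during warmup (first 50% of each chain, the common
default since no warmup length is printed) and are frozen afterwards.
Two implementation details matter:

- block updates touch only the likelihood rows of their cell or dog, so
  a sweep costs O(n) row-likelihood evaluations;
- the cell means and the random intercepts of the dogs observed in them
  form a ridge (`beta + c`, `u - c` leaves the likelihood unchanged). A
  dedicated recentering move proposes exactly this shift per connected
  component of the cell–dog incidence graph and accepts on the priors
  alone. Without it, split R-hat on short chains stalled around 1.7;
  with it, the same chains reach ~1.1 or better.

Chains start from empirical cell-mean logits (shrunk 10% toward the
global mean) with chain-dispersed jitter; `phi` starts at a moment
estimate. Defaults are 4 chains x 10,000 iterations; the validation
experiments use 2 x 2,000, which the diagnostics support at the
simulated sizes. Fits are reproducible given the spec seed; reduced
models (`random_intercepts=False`, `fix_phi`) exist for oracle checks
against dense-grid quadrature.

**Diagnostics.** Split-chain potential scale reduction (R-hat), plain
(non-rank-normalised) by default since that matches the era of the
analysis being reproduced; zero-variance chains yield NaN with a
warning rather than an error.

**Summaries.** Equal-tailed quantile intervals at level 0.89 (the
reported convention): *fitted* intervals summarise the population mean
`softmax(beta_cell)` with random effects at zero; *predicted* intervals
draw one new composition from `Dirichlet(softmax(beta_cell) * phi)` per
posterior draw, adding the residual Dirichlet variation. Inter-subject
variation is excluded by default to match the reported interval
definition; `include_random_effects=True` draws a new dog's intercept
first. Points are posterior means of the population-mean composition in
both tables, so fitted points sum to one per cell.

Two known behaviours at small cluster sizes: the posterior of `phi`
tends to sit above the simulation truth (the zero adjustment lifts the
smallest observations, and dog intercepts absorb some residual
variation when each dog contributes only four samples), and per-cell
coefficients carry sampling noise of order `sigma_u / sqrt(dogs per
sequence)` from the random-intercept means. Neither materially harms
predictive calibration: the pooled coverage of 89% prediction intervals
across replicate simulations sits within binomial error of nominal (see
`scripts/acceptance.py`).

## Shannon linear mixed model

`shannon ~ Diet + Group + Diet:Group + (1 | DogID)` fitted by REML. With
a single random intercept the REML criterion is profiled down to the
variance ratio `gamma = sigma2_subject / sigma2_residual`; the
optimisation is 1-D (bounded Brent on log gamma), with `gamma = 0`
evaluated explicitly so boundary fits are exact rather than tiny
positives. Block structure is exploited through Woodbury identities, so
no n x n matrix is formed. Designs with one observation per subject are
rejected as non-identifiable rather than returned at a boundary.

Fixed effects use treatment coding with alphabetical reference
(configurable); rank-deficient designs raise an error listing the
aliased columns. Intervals are z-based Wald (the original analysis
reports package defaults without degrees-of-freedom detail;
Satterthwaite is out of scope). Marginal and conditional R² follow the
variance-decomposition definition: `var(X beta)` (sample variance of
fixed-effect predictions) over `var_f + sigma2_subject +
sigma2_residual`, with the conditional numerator adding
`sigma2_subject`. Estimated marginal means average the factor grid with
equal weights; pairwise contrasts offer a single-step max-|z|
(Tukey-style) adjustment computed from a large seeded Monte-Carlo
sample of the contrast correlation — robust to the singular contrast
covariance — plus Bonferroni and unadjusted options. Responses such as
predicted-pathway abundances can be log-transformed with a recorded
offset first.

## Pipeline and determinism

`RunConfig` is a flat, YAML-serialisable record of every stage toggle
and parameter; `validate_config` aggregates all violations into one
message (including cross-field rules such as chains >= 2 whenever the
Dirichlet stage runs, since split R-hat needs multiple chains). A run
writes the config next to its outputs, logs with timestamps to console
and file with machine-greppable `WARN` prefixes, and re-running an
identical config and seed reproduces numeric outputs byte for byte.

## Problem sizes in the tests

The suite exercises the pipeline at reduced sizes chosen so the full
statistical structure is present: recovery and calibration runs use 20
dogs, 5 categories, `phi = 100`, 2 chains x 2,000 iterations, and ten
replicates; the PERMANOVA null calibration uses 500 simulated datasets
of 12 samples with 99 permutations each. Larger runs sharpen the same
comparisons but do not change what is being tested.

## Known limitations

- The sampler is random-walk based; for many more categories or cells
  per dataset a gradient-based sampler would mix faster. At the sizes
  here the diagnostics are adequate.
- `phi` is shared across cells; heteroscedastic extensions (per-cell
  precision), zero-inflated and logistic-normal alternatives, and model
  comparison (WAIC/LOO) are out of scope.
- Only a single random-intercept term is supported in the mixed model —
  no crossed/nested random effects, no GLMMs.
- UniFrac and other phylogeny-aware metrics are out of scope; so is
  everything upstream of the count table (read QC, OTU picking,
  functional prediction).
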