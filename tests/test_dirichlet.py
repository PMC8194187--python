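import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from crossdiet import dirichlet as dm
from crossdiet import simulate as sim
from crossdiet.containers import CompositionTable


def _toy_data(y, cells=None, dogs=None, categories=None):
    """Assemble a ModelData directly from an array of compositions."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    categories = categories or [f"t{i}" for i in range(k)]
    return dm.ModelData(
        y=y,
        cell_index=np.asarray(cells if cells is not None else np.zeros(n, int)),
        dog_index=np.asarray(dogs if dogs is not None else np.zeros(n, int)),
        cells=["ACB:baseline"] if cells is None else
              [f"cell{i}" for i in range(max(cells) + 1)],
        dogs=["dog1"] if dogs is None else [f"dog{i}" for i in range(max(dogs) + 1)],
        categories=categories,
        sample_ids=[f"s{i}" for i in range(n)],
    )


class TestDirichletLogpdf:
    def test_uniform_density_is_log_two(self):
        # Dir(1,1,1) has constant density Gamma(3) = 2 on the 2-simplex
        for y in ([0.2, 0.3, 0.5], [0.6, 0.3, 0.1]):
            val = dm.dirichlet_logpdf(y, [1 / 3, 1 / 3, 1 / 3], 3.0)
            assert val == pytest.approx(np.log(2.0), abs=1e-12)

    def test_matches_log_gamma_oracle_on_random_points(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(2, 6)
            y = rng.dirichlet(np.ones(k) * 2)
            y = np.clip(y, 1e-9, None)
            y /= y.sum()
            mean = rng.dirichlet(np.ones(k) * 3)
            mean = np.clip(mean, 1e-6, None)
            mean /= mean.sum()
            phi = float(rng.uniform(0.5, 200))
            alpha = mean * phi
            oracle = (gammaln(alpha.sum()) - gammaln(alpha).sum()
                      + ((alpha - 1) * np.log(y)).sum())
            assert dm.dirichlet_logpdf(y, mean, phi) == pytest.approx(
                oracle, abs=1e-10)

    def test_k2_reduces_to_beta(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mu = float(rng.uniform(0.05, 0.95))
            phi = float(rng.uniform(0.5, 50))
            y1 = float(rng.uniform(0.01, 0.99))
            mine = dm.dirichlet_logpdf([y1, 1 - y1], [mu, 1 - mu], phi)
            beta = stats.beta.logpdf(y1, mu * phi, (1 - mu) * phi)
            assert mine == pytest.approx(beta, abs=1e-10)

    def test_density_integrates_to_one_k2(self):
        mu, phi = 0.3, 7.0
        val, err = integrate.quad(
            lambda t: np.exp(dm.dirichlet_logpdf([t, 1 - t], [mu, 1 - mu], phi)),
            0, 1, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            dm.dirichlet_logpdf([0.0, 1.0], [0.5, 0.5], 2.0)


class TestLogPosterior:
    def _state(self, k=3, cells=1, dogs=1, seed=0):
        rng = np.random.default_rng(seed)
        beta = np.zeros((cells, k))
        beta[:, 1:] = rng.normal(size=(cells, k - 1))
        u = np.zeros((dogs, k))
        u[:, 1:] = rng.normal(0, 0.3, size=(dogs, k - 1))
        return dm.ParamState(beta, u, np.log(np.full(k - 1, 0.5)), np.log(20.0))

    def test_zero_rows_equals_prior(self):
        spec = dm.ModelSpec(chains=2, iterations=8, seed=0)
        state = self._state()
        empty = _toy_data(np.empty((0, 3)))
        prior_only = dm.log_posterior(state, empty, spec)
        sd_u = np.exp(state.log_sd_u)
        expected = (
            stats.norm.logpdf(state.beta[:, 1:], 0, 5).sum()
            + stats.norm.logpdf(state.u[:, 1:], 0, sd_u).sum()
            + (stats.halfnorm.logpdf(sd_u, scale=2.5) + state.log_sd_u).sum()
            + stats.norm.logpdf(state.log_phi, np.log(30), 1.5))
        assert prior_only == pytest.approx(expected, abs=1e-10)

    def test_row_additivity(self):
        spec = dm.ModelSpec(chains=2, iterations=8, seed=0)
        state = self._state()
        rng = np.random.default_rng(2)
        rows = rng.dirichlet(np.ones(3) * 2, size=4)
        lp3 = dm.log_posterior(state, _toy_data(rows[:3]), spec)
        lp4 = dm.log_posterior(state, _toy_data(rows), spec)
        mu = sim.softmax(state.beta[0] + state.u[0])
        extra = dm.dirichlet_logpdf(rows[3], mu, np.exp(state.log_phi))
        assert lp4 - lp3 == pytest.approx(extra, abs=1e-9)

    def test_degenerate_sd_is_minus_inf(self):
        spec = dm.ModelSpec(chains=2, iterations=8, seed=0)
        state = self._state()
        state.log_sd_u = np.full(2, -500.0)  # sd_u -> 0 with u != 0
        rows = np.random.default_rng(3).dirichlet(np.ones(3), size=2)
        with np.errstate(over="ignore"):
            assert dm.log_posterior(state, _toy_data(rows), spec) == -np.inf


class TestBuildDesign:
    def test_cell_count_two_sequences_four_periods(self, small_trial,
                                                   small_composition):
        data = dm.build_design(small_trial.metadata, small_composition)
        assert len(data.cells) == 8

    def test_reference_reordering(self, small_trial, small_composition):
        data = dm.build_design(small_trial.metadata, small_composition,
                               reference="Firmicutes")
        assert data.categories[0] == "Firmicutes"
        assert sorted(data.categories) == sorted(small_composition.categories)

    def test_boundary_composition_rejected(self, small_trial):
        from crossdiet import composition as comp
        rel = comp.relative_abundance(small_trial.counts)
        has_zero = (rel.proportions.to_numpy() == 0).any()
        if not has_zero:
            values = rel.proportions.copy()
            values.iloc[0, 0] = 0.0
            values.iloc[0] /= values.iloc[0].sum()
            rel = CompositionTable(proportions=values)
        with pytest.raises(ValueError, match="strictly positive"):
            dm.build_design(small_trial.metadata, rel)

    def test_unknown_sample_named(self, small_trial, small_composition):
        meta = small_trial.metadata.iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            dm.build_design(meta, small_composition)


def _grid_posterior_mean(y_free, phi, prior_sd=5.0):
    """Dense-grid quadrature posterior mean of the single free logit.

    For the 1-cell, K=2, fixed-phi toy the model reduces to
    y_free ~ Beta(sigmoid(b) phi, (1-sigmoid(b)) phi) with b ~ N(0, 5).
    """
    grid = np.linspace(-6, 6, 4001)
    log_post = stats.norm.logpdf(grid, 0, prior_sd)
    for i, b in enumerate(grid):
        mu = 1.0 / (1.0 + np.exp(-b))
        log_post[i] += stats.beta.logpdf(y_free, mu * phi, (1 - mu) * phi).sum()
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    return float((grid * w).sum())


class TestSampler:
    def test_same_seed_identical_draws(self):
        rng = np.random.default_rng(4)
        y = rng.dirichlet((5, 3, 2), size=12)
        data = _toy_data(y)
        spec = dm.ModelSpec(chains=2, iterations=200, seed=11)
        d1 = dm.fit_mcmc(data, spec)
        d2 = dm.fit_mcmc(data, spec)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.phi, d2.phi)

    def test_posterior_mean_matches_grid_quadrature(self):
        # 1 cell, K=2, fixed phi, no random effects: a single free beta
        rng = np.random.default_rng(5)
        phi = 40.0
        true_mu = 0.65  # abundance of the free (second) category
        y = rng.dirichlet(((1 - true_mu) * phi, true_mu * phi), size=25)
        y = np.clip(y, 1e-9, None)
        y /= y.sum(axis=1, keepdims=True)
        data = _toy_data(y, categories=["ref", "free"])
        spec = dm.ModelSpec(chains=2, iterations=4000, seed=6,
                            random_intercepts=False, fix_phi=phi)
        draws = dm.fit_mcmc(data, spec)
        beta_draws = draws.beta[:, :, 0, 1].ravel()
        grid_mean = _grid_posterior_mean(y[:, 1], phi)
        mcse = beta_draws.std() / np.sqrt(len(beta_draws) / 20)  # lag-adjusted
        assert beta_draws.mean() == pytest.approx(grid_mean,
                                                  abs=max(4 * mcse, 0.02))


class TestRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(4, 4000))
        assert 0.99 < dm.rhat(arr) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(8)
        arr = np.vstack([rng.normal(0, 0.01, 500), rng.normal(10, 0.01, 500)])
        assert dm.rhat(arr) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            dm.rhat(np.random.default_rng(9).normal(size=(1, 100)))

    def test_zero_variance_is_nan(self):
        assert np.isnan(dm.rhat(np.ones((2, 100))))

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(10)
        arr = rng.normal(size=(3, 1000)) + rng.normal(0, 0.05, size=(3, 1))
        theirs = float(az.rhat(az.from_dict(posterior={"x": arr}),
                               method="split")["x"].values)
        assert dm.rhat(arr) == pytest.approx(theirs, abs=5e-3)


@pytest.fixture(scope="module")
def fitted_small_model():
    design = sim.TrialDesign(4, (0, 0))
    truth = sim.default_ground_truth(categories=4, design=design, phi=120.0,
                                     sigma_u=0.4, depth_range=(5_000, 20_000),
                                     seed=21)
    ds = sim.simulate_dataset(design, truth, seed=21)
    from crossdiet import composition as comp
    adj = comp.adjust_zeros(comp.relative_abundance(ds.counts), 1e-6)
    data = dm.build_design(ds.metadata, adj)
    spec = dm.ModelSpec(chains=2, iterations=1500, seed=22)
    return dm.fit_mcmc(data, spec)


class TestIntervals:
    def test_fitted_points_sum_to_one_per_cell(self, fitted_small_model):
        table = dm.fitted_intervals(fitted_small_model, level=0.89)
        sums = table.groupby("cell")["point"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_equal_tailed_quantiles_at_89(self, fitted_small_model):
        table = dm.fitted_intervals(fitted_small_model, level=0.89)
        draws = fitted_small_model
        mu = sim.softmax(draws.beta.reshape(-1, len(draws.cells),
                                            len(draws.categories)), axis=2)
        row = table.iloc[0]
        c = draws.cells.index(row.cell)
        k = draws.categories.index(row.category)
        assert row.lower == pytest.approx(np.quantile(mu[:, c, k], 0.055))
        assert row.upper == pytest.approx(np.quantile(mu[:, c, k], 0.945))

    def test_degenerate_draws_zero_width(self, fitted_small_model):
        frozen = dm.PosteriorDraws(
            beta=np.broadcast_to(fitted_small_model.beta[:1, :1],
                                 fitted_small_model.beta.shape).copy(),
            u=None, sd_u=None,
            phi=np.full_like(fitted_small_model.phi, 50.0),
            cells=fitted_small_model.cells, dogs=fitted_small_model.dogs,
            categories=fitted_small_model.categories, warmup=0, seed=0)
        table = dm.fitted_intervals(frozen, level=0.89)
        np.testing.assert_allclose(table.lower, table.point, atol=1e-12)
        np.testing.assert_allclose(table.upper, table.point, atol=1e-12)

    def test_predicted_contains_fitted(self, fitted_small_model):
        fitted = dm.fitted_intervals(fitted_small_model, level=0.89)
        predicted = dm.predicted_intervals(fitted_small_model, level=0.89,
                                           seed=1)
        merged = fitted.merge(predicted, on=["cell", "category"],
                              suffixes=("_fit", "_pred"))
        assert (merged.lower_pred <= merged.lower_fit + 1e-12).all()
        assert (merged.upper_pred >= merged.upper_fit - 1e-12).all()

    def test_large_phi_predicted_close_to_fitted(self):
        design = sim.TrialDesign(3, (0, 0))
        truth = sim.default_ground_truth(categories=3, design=design,
                                         phi=1e5, sigma_u=0.0,
                                         depth_range=(50_000, 60_000), seed=30)
        ds = sim.simulate_dataset(design, truth, seed=30)
        from crossdiet import composition as comp
        adj = comp.adjust_zeros(comp.relative_abundance(ds.counts), 1e-8)
        data = dm.build_design(ds.metadata, adj)
        spec = dm.ModelSpec(chains=2, iterations=1000, seed=31,
                            random_intercepts=False)
        draws = dm.fit_mcmc(data, spec)
        fitted = dm.fitted_intervals(draws, level=0.89)
        predicted = dm.predicted_intervals(draws, level=0.89, seed=2)
        merged = fitted.merge(predicted, on=["cell", "category"],
                              suffixes=("_fit", "_pred"))
        width_fit = merged.upper_fit - merged.lower_fit
        width_pred = merged.upper_pred - merged.lower_pred
        assert (width_pred - width_fit).max() < 0.02

    def test_bad_level_rejected(self, fitted_small_model):
        with pytest.raises(ValueError):
            dm.fitted_intervals(fitted_small_model, level=1.5)

    def test_softmax_shift_invariance(self):
        # adding a constant to a cell's full coefficient vector leaves the
        # reported composition unchanged
        rng = np.random.default_rng(12)
        eta = rng.normal(size=5)
        np.testing.assert_allclose(sim.softmax(eta), sim.softmax(eta + 3.7),
                                   atol=1e-12)


class TestExport:
    def test_long_frame_round_trip(self, fitted_small_model):
        frame = fitted_small_model.to_long_frame(["phi"])
        assert set(frame.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(frame) == (fitted_small_model.n_chains
                              * fitted_small_model.n_draws)
        back = frame.pivot(index="iteration", columns="chain", values="value")
        np.testing.assert_allclose(back.to_numpy().T, fitted_small_model.phi)
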