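import itertools

import numpy as np
import pandas as pd
import pytest

from crossdiet import diversity as dv
from crossdiet.containers import CountTable

from conftest import make_composition


def _table(values, samples=None):
    values = np.asarray(values)
    samples = samples or [f"s{i}" for i in range(1, values.shape[1] + 1)]
    counts = pd.DataFrame(values, columns=samples,
                          index=[f"f{i}" for i in range(values.shape[0])])
    return CountTable(counts=counts)


class TestRarefy:
    def test_column_sums_exactly_depth(self):
        rng = np.random.default_rng(0)
        table = _table(rng.integers(0, 2_000, size=(30, 5)))
        depth = int(table.sample_totals.min())
        rare = dv.rarefy(table, depth, seed=1)
        assert (rare.sample_totals == depth).all()

    def test_depth_equal_total_unchanged(self):
        table = _table([[5], [7], [3]])
        rare = dv.rarefy(table, 15, seed=0)
        pd.testing.assert_frame_equal(rare.counts, table.counts)

    def test_never_exceeds_original(self):
        rng = np.random.default_rng(2)
        table = _table(rng.integers(0, 500, size=(20, 4)))
        for seed in range(5):
            rare = dv.rarefy(table, 100, seed=seed)
            assert (rare.counts.to_numpy()
                    <= table.counts[rare.samples].to_numpy()).all()

    def test_shallow_samples_dropped(self):
        table = _table([[100, 3], [100, 2]], samples=["deep", "shallow"])
        rare = dv.rarefy(table, 50, seed=0)
        assert rare.samples == ["deep"]

    def test_reproducible_and_unbiased(self):
        table = _table([[600], [300], [100]])
        r1 = dv.rarefy(table, 100, seed=3)
        r2 = dv.rarefy(table, 100, seed=3)
        pd.testing.assert_frame_equal(r1.counts, r2.counts)
        # expectation = depth * proportion (hypergeometric mean), Monte Carlo
        draws = np.array([dv.rarefy(table, 100, seed=s).counts["s1"].to_numpy()
                          for s in range(300)])
        np.testing.assert_allclose(draws.mean(axis=0), [60, 30, 10], atol=1.5)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            dv.rarefy(_table([[5]]), 0)


class TestShannon:
    @pytest.mark.parametrize("vec, expected", [
        ([1, 1, 1, 1], 2.0),          # uniform over 4, base 2
        ([10, 0, 0], 0.0),            # single taxon
        ([2, 1, 1], 1.5),             # hand computation
    ])
    def test_closed_forms(self, vec, expected):
        assert dv.shannon(vec, base=2) == pytest.approx(expected)

    def test_bounded_by_log_k_and_maximal_iff_uniform(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vec = rng.dirichlet(np.ones(6))
            assert dv.shannon(vec) <= np.log2(6) + 1e-12
        assert dv.shannon(np.ones(6)) == pytest.approx(np.log2(6))

    def test_natural_log_option(self):
        assert dv.shannon([1, 1], base=np.e) == pytest.approx(np.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.shannon([0, 0])


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert dv.bray_curtis([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_is_one(self):
        assert dv.bray_curtis([5, 0], [0, 7]) == 1.0

    def test_hand_value(self):
        assert dv.bray_curtis([6, 2], [2, 2]) == pytest.approx(1 / 3)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.bray_curtis([0, 0], [0, 0])

    def test_matrix_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(6, 10))
        table = _table(counts.T)
        mine = dv.bray_curtis_matrix(table)
        theirs = skbio_distance.beta_diversity("braycurtis", counts,
                                               ids=table.samples)
        np.testing.assert_allclose(mine.to_numpy(), theirs.data, atol=1e-12)


class TestPcoa:
    def test_collinear_three_points(self):
        dm = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                          index=list("abc"), columns=list("abc"), dtype=float)
        res = dv.pcoa(dm)
        assert res.coordinates.shape[1] == 1
        assert res.proportion_explained.iloc[0] == pytest.approx(1.0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(6)
        points = rng.normal(size=(8, 2))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        dm = pd.DataFrame(d, index=[f"s{i}" for i in range(8)],
                          columns=[f"s{i}" for i in range(8)])
        res = dv.pcoa(dm)
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_two_samples_gap_equals_distance(self):
        dm = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"],
                          columns=["a", "b"])
        res = dv.pcoa(dm)
        gap = abs(res.coordinates.iloc[0, 0] - res.coordinates.iloc[1, 0])
        assert gap == pytest.approx(0.4)

    def test_non_symmetric_rejected(self):
        dm = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            dv.pcoa(dm)

    def test_variance_shares_match_skbio(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        skbio_dm = pytest.importorskip("skbio").DistanceMatrix
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 60, size=(7, 12))
        dm = dv.bray_curtis_matrix(_table(counts.T))
        mine = dv.pcoa(dm)
        theirs = skbio_pcoa(skbio_dm(dm.to_numpy(), ids=list(dm.index)))
        n_pos = len(mine.proportion_explained)
        np.testing.assert_allclose(
            mine.proportion_explained.to_numpy()[:2],
            theirs.proportion_explained.to_numpy()[:2], atol=1e-8)


def _two_cluster_setup():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 0.05, size=(6, 4)) + [10, 0, 0, 0]
    b = rng.normal(0, 0.05, size=(6, 4)) + [0, 10, 0, 0]
    pts = np.abs(np.vstack([a, b]))
    ids = [f"s{i}" for i in range(12)]
    dm = dv.bray_curtis_matrix(pd.DataFrame(pts, index=ids))
    meta = pd.DataFrame({"cluster": ["x"] * 6 + ["y"] * 6}, index=ids)
    return dm, meta


class TestPermanova:
    def test_separable_clusters(self):
        dm, meta = _two_cluster_setup()
        res = dv.permanova(dm, meta, ["cluster"], n_permutations=99, seed=0)
        assert res.r_squared("cluster") > 0.95
        assert res.p_value("cluster") == pytest.approx(1 / 100)

    def test_r_squared_sums_to_one(self, small_trial):
        dm = dv.bray_curtis_matrix(small_trial.counts)
        res = dv.permanova(dm, small_trial.metadata, ["Diet", "Group"],
                           n_permutations=99, seed=1)
        assert res.table["r_squared"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_pseudo_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        dm, meta = _two_cluster_setup()
        mine = dv.permanova(dm, meta, ["cluster"], n_permutations=999, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            meta["cluster"].to_numpy(), permutations=999)
        f_mine = float(mine.table.set_index("term").loc["cluster", "pseudo_f"])
        assert f_mine == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_exact_enumeration_n6(self):
        # brute-force p-value over all 720 label orderings vs sampled p
        rng = np.random.default_rng(9)
        pts = np.abs(rng.normal(1, 0.4, size=(6, 3)))
        ids = [f"s{i}" for i in range(6)]
        dm = dv.bray_curtis_matrix(pd.DataFrame(pts, index=ids))
        labels = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
        meta = pd.DataFrame({"grp": labels}, index=ids)

        def pseudo_f(lab):
            d2 = dm.to_numpy() ** 2
            n = 6
            ss_total = d2[np.triu_indices(n, 1)].sum() / n
            ss_within = 0.0
            for g in np.unique(lab):
                idx = np.flatnonzero(lab == g)
                ss_within += d2[np.ix_(idx, idx)][
                    np.triu_indices(len(idx), 1)].sum() / len(idx)
            ss_between = ss_total - ss_within
            return (ss_between / 1) / (ss_within / 4)

        f_obs = pseudo_f(labels)
        exceed = sum(pseudo_f(labels[list(perm)]) >= f_obs - 1e-12
                     for perm in itertools.permutations(range(6)))
        p_exact = exceed / 720
        res = dv.permanova(dm, meta, ["grp"], n_permutations=999, seed=2)
        f_mine = float(res.table.set_index("term").loc["grp", "pseudo_f"])
        assert f_mine == pytest.approx(f_obs, rel=1e-10)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value("grp") - p_exact) < 4 * se + 2 / 999

    def test_single_level_term_rejected(self):
        dm, meta = _two_cluster_setup()
        meta["const"] = "same"
        with pytest.raises(ValueError, match="single level"):
            dv.permanova(dm, meta, ["const"], n_permutations=99)

    def test_strata_permutation_respects_groups(self):
        # label constant within strata: every within-stratum shuffle leaves
        # the labelling intact, the permutation distribution is degenerate
        # and the p-value sits at 1 (all ties)
        dm, meta = _two_cluster_setup()
        meta["dog"] = meta["cluster"]
        res = dv.permanova(dm, meta, ["cluster"], n_permutations=99, seed=3,
                           strata="dog")
        assert res.p_value("cluster") == pytest.approx(1.0)


class TestDistanceToBaseline:
    def test_identical_sample_zero_distance(self, small_trial):
        dm = dv.bray_curtis_matrix(small_trial.counts)
        out = dv.distance_to_baseline(dm, small_trial.metadata)
        dog = out[out.DogID == "dog1_01"]
        base_id = "dog1_01.baseline"
        for _, row in dog.iterrows():
            expected = dm.loc[base_id, f"dog1_01.{row.Period}"]
            assert row.distance == pytest.approx(expected)

    def test_bookkeeping_two_dogs(self):
        ids = [f"d{i}.{p}" for i in (1, 2)
               for p in ("baseline", "phase1", "washout", "phase2")]
        rng = np.random.default_rng(10)
        pts = np.abs(rng.normal(1, 0.3, size=(8, 3)))
        dm = dv.bray_curtis_matrix(pd.DataFrame(pts, index=ids))
        meta = pd.DataFrame({
            "DogID": [f"d{i}" for i in (1, 2) for _ in range(4)],
            "Period": ["baseline", "phase1", "washout", "phase2"] * 2,
            "Diet": ["C", "A", "C", "B"] * 2,
        }, index=ids)
        out = dv.distance_to_baseline(dm, meta)
        assert len(out) == 6

    def test_invariant_to_sample_order(self):
        ids = ["d1.baseline", "d1.phase1", "d2.baseline", "d2.phase1"]
        rng = np.random.default_rng(11)
        pts = np.abs(rng.normal(1, 0.3, size=(4, 3)))
        dm = dv.bray_curtis_matrix(pd.DataFrame(pts, index=ids))
        meta = pd.DataFrame({
            "DogID": ["d1", "d1", "d2", "d2"],
            "Period": ["baseline", "phase1"] * 2,
            "Diet": ["C", "A"] * 2,
        }, index=ids)
        out1 = dv.distance_to_baseline(dm, meta)
        shuffled = dm.loc[ids[::-1], ids[::-1]]
        out2 = dv.distance_to_baseline(shuffled, meta)
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_baseline_skipped(self, caplog):
        ids = ["d1.phase1", "d2.baseline", "d2.phase1"]
        dm = pd.DataFrame(np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]),
                          index=ids, columns=ids)
        meta = pd.DataFrame({
            "DogID": ["d1", "d2", "d2"],
            "Period": ["phase1", "baseline", "phase1"],
            "Diet": ["A", "C", "A"],
        }, index=ids)
        out = dv.distance_to_baseline(dm, meta)
        assert set(out.DogID) == {"d2"}
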