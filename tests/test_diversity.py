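import numpy as np
import pandas as pd
import pytest

from mycolink import (
    DistanceMatrix,
    OtuTable,
    SimulationConfig,
    alpha_over_rarefactions,
    bray_curtis,
    permanova,
    rarefy_once,
    simulate_otu_table,
    within_among_test,
)


def _table(counts, groups=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"s{i}" for i in range(len(counts))]
    counts.columns = [f"o{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "host": "A",
            "inoculum": groups if groups is not None else "A",
            "compartment": "soil",
        },
        index=counts.index,
    )
    return OtuTable(counts, meta)


class TestRarefaction:
    def test_exhaustive_draw_is_identity(self):
        t = _table([[10, 5, 3]])
        out = rarefy_once(t, 18, seed=0)
        assert out.counts.values.tolist() == [[10, 5, 3]]

    def test_depth_one_draws_single_read(self):
        t = _table([[10, 5, 3], [2, 2, 2]])
        out = rarefy_once(t, 1, seed=1)
        assert (out.counts.sum(axis=1) == 1).all()
        assert ((out.counts == 1).sum(axis=1) == 1).all()

    def test_shallow_sample_raises_with_names(self):
        t = _table([[10, 5, 3], [1, 1, 0]])
        with pytest.raises(ValueError, match="s1"):
            rarefy_once(t, 10, seed=0)

    def test_mean_matches_hypergeometric_expectation(self):
        # sample (60, 40), depth 50: E[drawn OTU0] = 50 * 60/100 = 30
        t = _table([[60, 40]])
        rng = np.random.default_rng(123)
        draws = np.array(
            [rarefy_once(t, 50, rng).counts.iloc[0, 0] for _ in range(10_000)]
        )
        var = 50 * 0.6 * 0.4 * (100 - 50) / (100 - 1)  # hypergeometric variance
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - 30.0) < 3 * se

    def test_mean_richness_nondecreasing_in_depth(self):
        cfg = SimulationConfig(rng_seed=4, n_otus=40, block_spec={},
                               library_size_range=(3000, 4000),
                               n_low_depth_samples=0)
        t = simulate_otu_table(cfg, "soil")
        shallow = alpha_over_rarefactions(t, depth=50, reps=200, seed=0)
        deep = alpha_over_rarefactions(t, depth=1000, reps=200, seed=0)
        assert (deep["richness"] >= shallow["richness"] - 1e-9).all()


class TestAlpha:
    def test_single_otu_sample(self):
        t = _table([[500, 0]])
        alpha = alpha_over_rarefactions(t, depth=100, reps=10, seed=0)
        assert alpha["richness"].iloc[0] == 1.0
        assert alpha["shannon"].iloc[0] == 0.0

    def test_even_community_approaches_ln_s(self):
        t = _table([[25_000, 25_000, 25_000, 25_000]])
        alpha = alpha_over_rarefactions(t, depth=50_000, reps=20, seed=1)
        assert alpha["shannon"].iloc[0] == pytest.approx(np.log(4), abs=5e-3)
        assert alpha["shannon"].iloc[0] <= np.log(alpha["richness"].iloc[0]) + 1e-12

    def test_equal_base_richness_rarely_rejected(self):
        """Inocula built from the same species pool should show no richness
        differences: one-way ANOVA on mean richness stays null in >=90% of
        repeats."""
        from scipy.stats import f_oneway

        rejections = 0
        n_rep = 60
        rng = np.random.default_rng(99)
        shape = np.sort(rng.gamma(0.8, size=60))  # one shared abundance profile
        for seed in range(n_rep):
            perm_rng = np.random.default_rng(seed + 1000)
            # inocula are permutations of the same profile: identical expected
            # richness, different composition
            base = {i: shape[perm_rng.permutation(60)] for i in "ABCD"}
            cfg = SimulationConfig(
                rng_seed=seed,
                n_otus=60,
                block_spec={},
                base_proportions=base,
                library_size_range=(2000, 3000),
                n_low_depth_samples=0,
            )
            t = simulate_otu_table(cfg, "soil")
            alpha = alpha_over_rarefactions(t, depth=1500, reps=20, seed=seed)
            groups = [
                alpha.loc[ids, "richness"]
                for _, ids in t.sample_meta.groupby("inoculum").groups.items()
            ]
            if f_oneway(*groups).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        t = _table([[6, 2], [6, 2], [2, 2], [0, 7]])
        d = bray_curtis(t).to_dataframe()
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1 / 3)  # 1 - 2*4/12
        t2 = _table([[5, 0], [0, 9]])
        assert bray_curtis(t2).data[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 50, size=(6, 8))
        counts[:, 0] += 1  # no all-zero sample
        d = bray_curtis(_table(counts)).data
        for i in range(6):
            for j in range(6):
                x, y = counts[i].astype(float), counts[j].astype(float)
                expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
                assert d[i, j] == pytest.approx(expected)

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(_table([[1, 1], [0, 0]]))


class TestWithinAmong:
    def test_constant_distances_give_null_result(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        dist = DistanceMatrix([f"s{i}" for i in range(n)], d * 0.5)
        res = within_among_test(dist, pd.Series(["g1", "g1", "g2", "g2"],
                                                index=dist.ids))
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_separated_clusters_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.05, size=(5, 3)) + [1, 0, 0]
        b = rng.normal(0, 0.05, size=(5, 3)) + [0, 1, 0]
        counts = np.abs(np.vstack([a, b])) * 100 + 1
        t = _table(counts.astype(int), groups=["g1"] * 5 + ["g2"] * 5)
        dist = bray_curtis(t)
        res = within_among_test(dist, t.sample_meta["inoculum"])
        assert res["mean_within"] < res["mean_among"]
        assert res["p"] < 0.05

    def test_single_group_raises(self):
        d = np.array([[0, 0.5], [0.5, 0]])
        dist = DistanceMatrix(["s0", "s1"], d)
        with pytest.raises(ValueError, match="empty"):
            within_among_test(dist, pd.Series(["g", "g"], index=dist.ids))


class TestPermanova:
    def _clustered(self, seed=0, sep=1.0, n_per=5):
        rng = np.random.default_rng(seed)
        a = np.abs(rng.normal(1, 0.3, size=(n_per, 4))) + sep * np.array([4, 0, 0, 0])
        b = np.abs(rng.normal(1, 0.3, size=(n_per, 4))) + sep * np.array([0, 4, 0, 0])
        counts = (np.vstack([a, b]) * 50).astype(int) + 1
        return _table(counts, groups=["g1"] * n_per + ["g2"] * n_per)

    def test_r2_partition_sums_to_one(self):
        t = self._clustered()
        res = permanova(bray_curtis(t), t.sample_meta[["inoculum"]],
                        n_perm=99, seed=0)
        terms = res.drop(index="Total")
        assert terms["R2"].sum() == pytest.approx(1.0)
        assert ((terms["R2"] >= -1e-12) & (terms["R2"] <= 1 + 1e-12)).all()
        p = res.loc["inoculum", "p"]
        assert 0 < p <= 1

    def test_disjoint_groups_give_r2_near_one_and_min_p(self):
        counts = np.zeros((10, 8), dtype=int)
        counts[:5, :4] = 50
        counts[5:, 4:] = 50
        t = _table(counts, groups=["g1"] * 5 + ["g2"] * 5)
        res = permanova(bray_curtis(t), t.sample_meta[["inoculum"]],
                        n_perm=999, seed=1)
        assert res.loc["inoculum", "R2"] > 0.95
        # the smallest attainable p is set by label exchangeability: only a
        # permutation reproducing the 5|5 split ties the observed F, an event
        # of probability 2 * 5! * 5! / 10! = 1/126 per permutation
        assert res.loc["inoculum", "p"] <= (1 + 999 / 126 * 3) / 1000

    def test_single_level_factor_raises(self):
        t = self._clustered()
        with pytest.raises(ValueError, match="single level"):
            permanova(bray_curtis(t), t.sample_meta[["host"]], n_perm=99)

    def test_matches_skbio_pseudo_f(self):
        """Independent oracle: single-factor pseudo-F equals scikit-bio's."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        t = self._clustered(seed=5, sep=0.3)
        dist = bray_curtis(t)
        res = permanova(dist, t.sample_meta[["inoculum"]], n_perm=99, seed=0)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dist.data, ids=dist.ids),
            t.sample_meta["inoculum"].tolist(),
            permutations=99,
        )
        assert res.loc["inoculum", "pseudo_F"] == pytest.approx(
            float(sk["test statistic"]), rel=1e-9
        )

    def test_type_one_error_calibrated(self):
        """Free label permutation under a true null: rejection rate at
        alpha = 0.05 stays within 0.05 +/- 0.03 over 200 simulations."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            counts = rng.integers(1, 60, size=(12, 6))
            labels = ["g1"] * 6 + ["g2"] * 6
            t = _table(counts, groups=labels)
            res = permanova(
                bray_curtis(t), t.sample_meta[["inoculum"]], n_perm=99, seed=rng
            )
            if res.loc["inoculum", "p"] <= 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.03
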