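"""Community-profile operations against hand oracles and known formulas."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutweave.community import (
    alpha_diversity,
    filter_low_count_asvs,
    group_compare,
    log_transform,
    min_depth,
    ordinate,
    rarefy,
)
from gutweave.containers import CountTable
from gutweave.simulate import CommunitySimConfig, simulate_asv_table, simulate_tree


def _table(counts_dict, index):
    n = len(counts_dict)
    meta = pd.DataFrame(
        {"diet": ["control"] * n, "timepoint": [68] * n, "source": ["gut"] * n},
        index=list(counts_dict),
    )
    return CountTable(pd.DataFrame(counts_dict, index=index), meta)


class TestFilter:
    def test_boundary_at_threshold(self):
        t = _table({"s0": [1, 2, 0], "s1": [1, 1, 0]}, ["a", "b", "c"])
        # totals: a=2, b=3, c=0 -> only b survives "<= 2 counts" exclusion
        kept = filter_low_count_asvs(t, 2)
        assert kept.taxa == ["b"]
        assert kept.samples == t.samples

    def test_zero_threshold_identity_on_positive(self):
        t = _table({"s0": [3, 4], "s1": [1, 2]}, ["a", "b"])
        assert filter_low_count_asvs(t, 0).taxa == ["a", "b"]

    def test_negative_threshold_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            filter_low_count_asvs(tiny_table, -1)

    def test_oracle_recount_on_simulation(self):
        table, _ = simulate_asv_table(
            CommunitySimConfig(n_taxa=40, n_samples_per_group=5,
                               groups=[("control", 68)],
                               depth_range=(50, 200), seed=11)
        )
        kept = filter_low_count_asvs(table, 2)
        expected = [t for t in table.taxa if table.counts.loc[t].sum() > 2]
        assert kept.taxa == expected


class TestRarefy:
    def test_column_sums_equal_depth(self, tiny_table):
        r = rarefy(tiny_table, 10, seed=0)
        assert (r.sample_totals() == 10).all()

    def test_full_depth_sample_unchanged(self):
        t = _table({"s0": [5, 3], "s1": [20, 10]}, ["a", "b"])
        r = rarefy(t, 8, seed=1)
        assert r.counts["s0"].tolist() == [5, 3]

    def test_shallow_samples_dropped(self):
        t = _table({"s0": [5, 3], "s1": [2, 1]}, ["a", "b"])
        r = rarefy(t, 8, seed=1)
        assert r.samples == ["s0"]

    def test_hypergeometric_mean(self):
        """Mean rarefied count over many seeds matches depth x proportion."""
        t = _table({"s0": [60, 30, 10]}, ["a", "b", "c"])
        depth = 50
        sums = np.zeros(3)
        n_rep = 500
        for seed in range(n_rep):
            sums += rarefy(t, depth, seed=seed).counts["s0"].to_numpy()
        expected = depth * np.array([0.6, 0.3, 0.1])
        assert np.allclose(sums / n_rep, expected, rtol=0.02)

    def test_invalid_depth(self, tiny_table):
        with pytest.raises(ValueError):
            rarefy(tiny_table, 0)


class TestAlphaDiversity:
    def test_uniform_four_taxa(self):
        t = _table({"s0": [5, 5, 5, 5]}, list("abcd"))
        a = alpha_diversity(t, ("shannon", "invsimpson"))
        assert a.loc["s0", "shannon"] == pytest.approx(np.log(4))
        assert a.loc["s0", "invsimpson"] == pytest.approx(4.0)

    def test_chao1_hand_value(self):
        # S_obs=5, F1=2 singletons, F2=1 doubleton -> 5 + 4/2 = 7
        t = _table({"s0": [1, 1, 2, 5, 9]}, list("abcde"))
        a = alpha_diversity(t, ("observed", "chao1"))
        assert a.loc["s0", "observed"] == 5
        assert a.loc["s0", "chao1"] == pytest.approx(7.0)

    def test_single_taxon(self):
        t = _table({"s0": [7, 0]}, ["a", "b"])
        a = alpha_diversity(t, ("shannon", "invsimpson"))
        assert a.loc["s0", "shannon"] == 0.0
        assert a.loc["s0", "invsimpson"] == pytest.approx(1.0)

    def test_observed_le_chao1_invariant(self):
        table, _ = simulate_asv_table(
            CommunitySimConfig(n_taxa=30, n_samples_per_group=6,
                               groups=[("control", 68)],
                               depth_range=(100, 500), seed=3)
        )
        a = alpha_diversity(table, ("observed", "chao1"))
        assert (a["observed"] <= a["chao1"] + 1e-9).all()

    def test_faith_pd_single_taxon_path(self):
        from skbio import TreeNode

        nwk = "((a:1.0,b:2.0):0.5,c:3.0);"
        tree = TreeNode.read(io.StringIO(nwk))
        t = _table({"s0": [4, 0, 0]}, ["a", "b", "c"])
        a = alpha_diversity(t, ("pd",), tree=tree)
        # root-to-leaf path of taxon a: 1.0 + 0.5
        assert a.loc["s0", "pd"] == pytest.approx(1.5)

    def test_row_order_invariance(self, tiny_table):
        a1 = alpha_diversity(tiny_table, ("shannon", "chao1"))
        shuffled = CountTable(tiny_table.counts.iloc[::-1], tiny_table.metadata)
        a2 = alpha_diversity(shuffled, ("shannon", "chao1"))
        pd.testing.assert_frame_equal(a1, a2)


class TestLogTransform:
    def test_examples(self, tiny_table):
        ab = tiny_table.relative_abundance()
        out = log_transform(ab)
        p = ab.abundances
        assert out.to_numpy()[p.to_numpy() == 0].sum() == 0.0
        assert np.allclose(out.to_numpy(), np.log10(10_000 * p.to_numpy() + 1))

    def test_full_abundance_value(self):
        t = _table({"s0": [9]}, ["a"])
        out = log_transform(t.relative_abundance())
        assert out.loc["a", "s0"] == pytest.approx(np.log10(10_001), abs=1e-9)

    def test_monotone(self):
        x = np.linspace(0, 1, 50)
        y = np.log10(10_000 * x + 1)
        assert (np.diff(y) > 0).all()


class TestOrdinate:
    def test_pca_matches_eigh_oracle(self, rng):
        y = pd.DataFrame(rng.normal(size=(15, 6)))
        y = (y - y.mean()) / y.std(ddof=0)
        res = ordinate(y)
        cov = np.cov(y.to_numpy().T, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = 100 * eig / eig.sum()
        assert np.allclose(res.percent_explained, expected[: len(res.percent_explained)],
                           atol=1e-8)

    def test_pca_percents_conserve(self, rng):
        y = pd.DataFrame(rng.normal(size=(10, 4)))
        res = ordinate(y)
        assert res.percent_explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_perfect_fit_minimal_p(self, rng):
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        y = pd.get_dummies(pd.Series(labels)).astype(float)
        y += 1e-6 * rng.normal(size=y.shape)  # break exact permutation ties
        res = ordinate(y, labels, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_permutation_p_reproducible(self, rng):
        y = pd.DataFrame(rng.normal(size=(12, 5)))
        labels = ["a"] * 6 + ["b"] * 6
        p1 = ordinate(y, labels, n_perm=99, seed=42).p_value
        p2 = ordinate(y, labels, n_perm=99, seed=42).p_value
        assert p1 == p2

    def test_constant_matrix_rejected(self):
        y = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            ordinate(y)

    def test_null_calibration(self):
        """With labels independent of the response, p > 0.05 in ~95% of runs."""
        master = np.random.default_rng(7)
        n_runs, nonsig = 100, 0
        for _ in range(n_runs):
            y = pd.DataFrame(master.normal(size=(12, 4)))
            labels = ["a"] * 6 + ["b"] * 6
            res = ordinate(y, labels, n_perm=99,
                           seed=int(master.integers(2**31 - 1)))
            nonsig += res.p_value > 0.05
        assert nonsig >= 0.88 * n_runs


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        res = group_compare(vals, ["a"] * 4 + ["b"] * 4)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_power_on_shifted_normals(self):
        master = np.random.default_rng(1)
        hits = 0
        n_runs = 60
        for _ in range(n_runs):
            a = master.normal(0, 1, 20)
            b = master.normal(3, 1, 20)
            res = group_compare(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 20)
            hits += res.p_value < 0.01
        assert hits >= 0.95 * n_runs

    def test_gate_routes_heavy_tails_to_kruskal(self):
        master = np.random.default_rng(2)
        kruskal = 0
        n_runs = 50
        for _ in range(n_runs):
            a = master.standard_cauchy(20)
            b = master.standard_cauchy(20)
            res = group_compare(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 20)
            kruskal += res.test == "kruskal"
        assert kruskal >= 0.90 * n_runs

    def test_constant_group_falls_back(self):
        res = group_compare([1, 1, 1, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert res.test == "kruskal"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "b"])


def test_min_depth_skips_failed_samples():
    counts = pd.DataFrame({"s0": [5000, 5000], "s1": [2, 0], "s2": [3000, 1000]},
                          index=["a", "b"])
    meta = pd.DataFrame({"diet": ["control"] * 3, "timepoint": [68] * 3,
                         "source": ["gut"] * 3}, index=["s0", "s1", "s2"])
    assert min_depth(CountTable(counts, meta)) == 4000
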