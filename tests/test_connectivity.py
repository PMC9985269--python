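"""Co-occurrence network construction against enumeration and set oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutweave.connectivity import (
    NetworkConfig,
    build_network,
    classify_edges,
    eligible_taxa,
    pairwise_association,
    significant_pair_summary,
)
from gutweave.containers import AbundanceTable, CountTable
from gutweave.simulate import CommunitySimConfig, simulate_asv_table


def _group_table(counts, taxa):
    n = counts.shape[1]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({"diet": ["control"] * n, "timepoint": [68] * n,
                         "source": ["gut"] * n}, index=samples)
    return CountTable(pd.DataFrame(counts, index=taxa, columns=samples), meta)


def _abundance(df):
    n = df.shape[1]
    meta = pd.DataFrame({"diet": ["x"] * n, "timepoint": [68] * n,
                         "source": ["gut"] * n}, index=df.columns)
    return AbundanceTable(df.div(df.sum(axis=0), axis=1), meta)


class TestEligibility:
    def test_prevalence_boundary(self):
        # taxon u: present in 3/10 at high ppm -> kept; v: 2/10 -> dropped
        counts = np.zeros((3, 10), dtype=int)
        counts[0, :3] = 500
        counts[1, :2] = 500
        counts[2] = 10_000  # filler keeps totals positive
        t = _group_table(counts, ["u", "v", "w"])
        kept = eligible_taxa(t, NetworkConfig(), t.samples)
        assert "u" in kept and "v" not in kept

    def test_abundance_boundary_below_10ppm(self):
        total = 1_000_000
        low = 9  # 9 ppm mean in every sample
        counts = np.vstack([
            np.full(10, low),
            np.full(10, total - low),
        ])
        t = _group_table(counts, ["low", "big"])
        kept = eligible_taxa(t, NetworkConfig(), t.samples)
        assert "low" not in kept and "big" in kept

    def test_oracle_recount(self):
        table, _ = simulate_asv_table(
            CommunitySimConfig(n_taxa=25, n_samples_per_group=10,
                               groups=[("control", 68)],
                               depth_range=(20_000, 100_000), seed=5)
        )
        cfg = NetworkConfig()
        kept = set(eligible_taxa(table, cfg, table.samples))
        rel = table.counts / table.counts.sum(axis=0)
        expected = {
            t for t in table.taxa
            if (table.counts.loc[t] > 0).sum() >= int(np.ceil(0.3 * 10))
            and rel.loc[t].mean() >= 10 / 1e6
        }
        assert kept == expected

    def test_empty_group_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            eligible_taxa(tiny_table, NetworkConfig(), [])


class TestAssociation:
    def test_monotone_pair_spearman_one(self):
        df = pd.DataFrame({f"s{i}": [x, 2 * x] for i, x in enumerate([1, 2, 3, 4, 5])},
                          index=["x", "y"])
        ab = _abundance(df + 1)
        # note: relative abundances of [x, 2x] are constant; use raw-scaled frame
        ab.abundances.loc["x"] = [0.1, 0.2, 0.3, 0.4, 0.5]
        ab.abundances.loc["y"] = [0.2, 0.4, 0.5, 0.6, 0.7]
        assoc = pairwise_association(ab, NetworkConfig(), ab.samples)
        assert assoc.loc[0, "r"] == pytest.approx(1.0)

    def test_exact_permutation_p_n4(self):
        """Perfectly concordant ranks at n=4: p = 2/24 by full enumeration."""
        df = pd.DataFrame(
            {"s0": [1.0, 1.0], "s1": [2.0, 3.0], "s2": [3.0, 6.0], "s3": [4.0, 10.0]},
            index=["x", "y"],
        )
        ab = _abundance(df)
        # relative abundance flips y ordering; set explicit monotone profiles
        ab.abundances.loc["x"] = [0.1, 0.2, 0.3, 0.4]
        ab.abundances.loc["y"] = [0.15, 0.25, 0.35, 0.45]
        cfg = NetworkConfig(p_mode="exact_permutation")
        assoc = pairwise_association(ab, cfg, ab.samples)
        assert assoc.loc[0, "p"] == pytest.approx(2 / 24)

    def test_asymptotic_close_to_exact_at_n10(self):
        master = np.random.default_rng(3)
        for _ in range(5):
            x = master.random(10)
            y = master.random(10)
            df = pd.DataFrame(np.vstack([x, y]) + 0.1, index=["x", "y"],
                              columns=[f"s{i}" for i in range(10)])
            ab = _abundance(df)
            exact = pairwise_association(
                ab, NetworkConfig(p_mode="exact_permutation", seed=1), ab.samples)
            asym = pairwise_association(ab, NetworkConfig(), ab.samples)
            assert abs(exact.loc[0, "p"] - asym.loc[0, "p"]) < 0.05

    def test_symmetry(self):
        master = np.random.default_rng(4)
        df = pd.DataFrame(master.random((2, 8)) + 0.1, index=["x", "y"],
                          columns=[f"s{i}" for i in range(8)])
        ab = _abundance(df)
        fwd = pairwise_association(ab, NetworkConfig(), ab.samples)
        flipped = AbundanceTable(ab.abundances.iloc[::-1], ab.metadata)
        rev = pairwise_association(flipped, NetworkConfig(), ab.samples)
        assert fwd.loc[0, "r"] == pytest.approx(rev.loc[0, "r"])
        assert fwd.loc[0, "p"] == pytest.approx(rev.loc[0, "p"])

    def test_zero_variance_pair_skipped(self):
        df = pd.DataFrame({"s0": [1.0, 5.0], "s1": [1.0, 6.0],
                           "s2": [1.0, 7.0], "s3": [1.0, 8.0]},
                          index=["const", "var"])
        ab = _abundance(df)
        ab.abundances.loc["const"] = 0.25
        ab.abundances.loc["var"] = [0.1, 0.2, 0.3, 0.4]
        assoc = pairwise_association(ab, NetworkConfig(), ab.samples)
        assert assoc.empty


class TestNetwork:
    def _assoc(self, ps):
        return pd.DataFrame(
            [{"taxon_a": f"t{i}", "taxon_b": f"u{i}", "r": 0.5 if i % 2 == 0 else -0.5,
              "p": p, "n": 10, "group": "g"} for i, p in enumerate(ps)]
        )

    def test_edge_boundary_inclusive(self):
        assoc = self._assoc([0.05, 0.1, 0.11])
        nodes = pd.Series(0.01, index=[f"t{i}" for i in range(3)] + [f"u{i}" for i in range(3)])
        net = build_network(assoc, NetworkConfig(), nodes)
        assert len(net.edges) == 2

    def test_empty_association_gives_nodes_only(self):
        nodes = pd.Series([0.5, 0.5], index=["a", "b"])
        net = build_network(self._assoc([]), NetworkConfig(), nodes)
        assert len(net.graph.nodes) == 2 and len(net.edges) == 0

    def test_edge_sign_matches_r(self):
        assoc = self._assoc([0.01, 0.02])
        nodes = pd.Series(0.1, index=["t0", "u0", "t1", "u1"])
        net = build_network(assoc, NetworkConfig(), nodes)
        for _, _, d in net.graph.edges(data=True):
            assert d["sign"] == ("co" if d["r"] > 0 else "anti")


class TestClassification:
    def _net(self, edges, universe):
        import networkx as nx

        from gutweave.connectivity import OccurrenceNetwork

        g = nx.Graph()
        g.add_nodes_from(universe)
        g.add_edges_from(edges)
        return OccurrenceNetwork(g)

    def test_partition_classes(self):
        universe = list("abcd")
        nets = {
            "control": self._net([("a", "b"), ("a", "c"), ("c", "d")], universe),
            "butyrate": self._net([("a", "b"), ("b", "c")], universe),
            "saponin": self._net([("a", "b"), ("b", "c")], universe),
        }
        out = classify_edges(nets).set_index(["taxon_a", "taxon_b"])
        assert out.loc[("a", "b"), "edge_class"] == "all-diets"
        assert out.loc[("a", "c"), "edge_class"] == "unique-to-control"
        assert out.loc[("b", "c"), "edge_class"] == "shared-partial"

    def test_set_algebra_oracle_on_random_networks(self, rng):
        universe = [f"t{i}" for i in range(8)]
        pairs = list(combinations(universe, 2))
        nets = {}
        edge_sets = {}
        for diet in ("control", "butyrate", "saponin"):
            chosen = [p for p in pairs if rng.random() < 0.3]
            nets[diet] = self._net(chosen, universe)
            edge_sets[diet] = {frozenset(p) for p in chosen}
        out = classify_edges(nets)
        for row in out.itertuples():
            pair = frozenset((row.taxon_a, row.taxon_b))
            expected = {d for d, es in edge_sets.items() if pair in es}
            assert set(row.diets) == expected

    def test_mismatched_universe_rejected(self):
        nets = {"a": self._net([], ["x", "y"]), "b": self._net([], ["x", "z"])}
        with pytest.raises(ValueError):
            classify_edges(nets)


class TestSummary:
    def test_count_at_threshold(self):
        assoc = pd.DataFrame({"taxon_a": list("abc"), "taxon_b": list("xyz"),
                              "r": [0.5] * 3, "p": [0.01, 0.04, 0.2],
                              "n": [10] * 3, "group": ["g"] * 3})
        out = significant_pair_summary({"g": assoc}, NetworkConfig())
        assert out.sig_counts["g"] == 2

    def test_reference_line(self):
        out = significant_pair_summary({}, NetworkConfig())
        assert out.reference == pytest.approx(1.3010, abs=5e-5)

    def test_cumulative_curve_reaches_one(self, rng):
        assoc = pd.DataFrame({"taxon_a": [f"a{i}" for i in range(20)],
                              "taxon_b": [f"b{i}" for i in range(20)],
                              "r": rng.random(20), "p": rng.random(20),
                              "n": [10] * 20, "group": ["g"] * 20})
        out = significant_pair_summary({"g": assoc}, NetworkConfig())
        curve = out.curves["g"]
        assert curve["cumulative_frequency"].iloc[-1] == pytest.approx(1.0)
        assert (curve["cumulative_frequency"].diff().dropna() >= 0).all()


def test_recovery_monotone_in_factor_strength():
    """Mean significant-pair count grows with the co-occurrence knob."""
    seeds = range(8)
    means = []
    for s in (0.0, 0.5, 0.9):
        counts = []
        for seed in seeds:
            cfg = CommunitySimConfig(n_taxa=10, n_samples_per_group=10,
                                     groups=[("control", 68)],
                                     n_latent_factors=5, factor_strength=s,
                                     depth_range=(10_000, 50_000), seed=seed)
            table, _ = simulate_asv_table(cfg)
            ab = table.relative_abundance()
            ncfg = NetworkConfig()
            taxa = eligible_taxa(table, ncfg, table.samples)
            assoc = pairwise_association(ab, ncfg, table.samples, taxa=taxa)
            counts.append(int((assoc["p"] <= 0.05).sum()))
        means.append(np.mean(counts))
    assert means[0] <= means[1] <= means[2]
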