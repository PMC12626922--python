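import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rhizonet import (
    FeatureTable,
    aggregate_to_genus,
    bh_adjust,
    build_network,
    per_group_networks,
    spearman_matrix,
    top_taxa,
    topology,
)
from ._oracles import brute_bh, brute_spearman


class TestAggregation:
    def test_same_genus_counts_sum(self, small_table, small_taxonomy):
        out = aggregate_to_genus(small_table, small_taxonomy)
        # ASV_1 and ASV_2 share GenA
        expected = small_table.data["ASV_1"] + small_table.data["ASV_2"]
        assert (out.data["GenA"] == expected).all()

    def test_total_count_conserved(self, small_table, small_taxonomy):
        out = aggregate_to_genus(small_table, small_taxonomy)
        assert out.counts.sum() == small_table.counts.sum()

    def test_unassigned_pools_by_next_rank(self, small_table, small_taxonomy):
        out = aggregate_to_genus(small_table, small_taxonomy)
        # ASV_4 lacks genus, family=F2 -> unclassified_F2;
        # ASV_5 lacks genus+family, phylum=Firmicutes -> unclassified_Firmicutes
        assert "unclassified_F2" in out.taxon_ids
        assert "unclassified_Firmicutes" in out.taxon_ids

    def test_missing_entry_raises_in_strict_mode(self, small_table, small_taxonomy):
        trimmed = small_taxonomy.assignments.drop(index="ASV_5")
        from rhizonet import TaxonomyMap

        with pytest.raises(KeyError):
            aggregate_to_genus(small_table, TaxonomyMap(trimmed))


class TestTopTaxa:
    def test_all_taxa_is_identity(self, small_table):
        assert top_taxa(small_table, small_table.n_taxa) == small_table

    def test_drops_least_abundant(self):
        df = pd.DataFrame(
            [[50, 30, 20], [50, 30, 20]], index=["s1", "s2"], columns=["a", "b", "c"]
        )
        out = top_taxa(FeatureTable(df), 2)
        assert out.taxon_ids == ["a", "b"]

    def test_tie_breaks_lexicographically(self):
        df = pd.DataFrame([[10, 10, 5]], index=["s1"], columns=["z", "a", "m"])
        out = top_taxa(FeatureTable(df), 1)
        assert out.taxon_ids == ["a"]

    def test_invalid_n_rejected(self, small_table):
        with pytest.raises(ValueError):
            top_taxa(small_table, 0)
        with pytest.raises(ValueError):
            top_taxa(small_table, 99)


class TestSpearman:
    def test_monotone_and_antitone_extremes(self):
        x = np.array([1.0, 2, 3, 4, 5])
        df = pd.DataFrame({"a": x, "b": np.exp(x), "c": -x})
        res = spearman_matrix(df)
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)
        assert res.rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_mid_rank_hand_example(self):
        # x=[1,2,2,4], y=[1,3,2,4] -> rho = 4.5/sqrt(4.5*5)
        df = pd.DataFrame({"x": [1, 2, 2, 4], "y": [1, 3, 2, 4]})
        res = spearman_matrix(df)
        assert res.rho.loc["x", "y"] == pytest.approx(4.5 / np.sqrt(4.5 * 5))

    def test_matches_brute_force_oracle_without_ties(self, rng):
        for _ in range(40):
            data = rng.normal(size=(12, 6))
            df = pd.DataFrame(data, columns=[f"t{i}" for i in range(6)])
            res = spearman_matrix(df)
            for i in range(6):
                for j in range(i + 1, 6):
                    expected = brute_spearman(data[:, i], data[:, j])
                    assert res.rho.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_p_values_match_scipy(self, rng):
        data = rng.normal(size=(15, 4))
        df = pd.DataFrame(data, columns=list("abcd"))
        res = spearman_matrix(df)
        for i in range(4):
            for j in range(i + 1, 4):
                rho, p = stats.spearmanr(data[:, i], data[:, j])
                assert res.rho.iloc[i, j] == pytest.approx(rho, abs=1e-12)
                assert res.p.iloc[i, j] == pytest.approx(p, abs=1e-10)

    def test_constant_taxon_flagged_and_nan(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=6), "b": np.ones(6), "c": rng.normal(size=6)})
        res = spearman_matrix(df)
        assert res.constant_taxa == ["b"]
        assert np.isnan(res.rho.loc["a", "b"])

    def test_too_few_samples_hard_error(self):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(pd.DataFrame({"a": [1, 2, 3], "b": [3, 2, 1]}))

    def test_sample_order_invariance(self, rng):
        data = rng.normal(size=(10, 5))
        df = pd.DataFrame(data, columns=list("abcde"))
        perm = rng.permutation(10)
        res1 = spearman_matrix(df)
        res2 = spearman_matrix(df.iloc[perm])
        assert np.allclose(res1.rho, res2.rho)
        assert np.allclose(res1.p_adj, res2.p_adj, equal_nan=True)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.03]), [0.015, 0.04, 0.04])

    def test_matches_brute_force_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            np.testing.assert_allclose(ours, brute_bh(p), atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, sm, atol=1e-12)

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_entries_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestBuildNetworkAndTopology:
    def _corr(self, df):
        return spearman_matrix(df)

    def test_weak_correlations_give_no_edges(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        net = build_network(self._corr(df))
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 5  # isolated nodes retained

    def test_perfect_pair_gives_positive_edge(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.cos(x * 37.7)})
        net = build_network(self._corr(df))
        assert net.has_edge("a", "b")
        assert net.edges["a", "b"]["sign"] == "+"

    def test_edges_shrink_as_thresholds_tighten(self, rng):
        base = rng.normal(size=(30, 1))
        data = base + 0.5 * rng.normal(size=(30, 8))
        df = pd.DataFrame(data, columns=[f"t{i}" for i in range(8)])
        corr = self._corr(df)
        loose = build_network(corr, rho_min=0.3, alpha=0.2)
        tight_rho = build_network(corr, rho_min=0.6, alpha=0.2)
        tight_alpha = build_network(corr, rho_min=0.3, alpha=0.01)
        assert set(tight_rho.edges()) <= set(loose.edges())
        assert set(tight_alpha.edges()) <= set(loose.edges())

    def test_invalid_thresholds_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        corr = self._corr(df)
        with pytest.raises(ValueError):
            build_network(corr, rho_min=1.5)
        with pytest.raises(ValueError):
            build_network(corr, alpha=0.0)

    def test_every_edge_satisfies_declared_thresholds(self, rng):
        base = rng.normal(size=(25, 1))
        df = pd.DataFrame(
            base + 0.4 * rng.normal(size=(25, 6)), columns=[f"t{i}" for i in range(6)]
        )
        net = build_network(self._corr(df), rho_min=0.5, alpha=0.1)
        for _, _, d in net.edges(data=True):
            assert abs(d["rho"]) >= 0.5
            assert d["p_adj"] < 0.1

    def test_topology_formulas(self):
        import networkx as nx

        k4 = nx.complete_graph(4)
        assert topology(k4).graph_density == pytest.approx(1.0)
        # printed-scale check: 437 edges on 100 nodes, 220 positive
        g = nx.gnm_random_graph(100, 437, seed=1)
        for idx, (u, v) in enumerate(g.edges()):
            g.edges[u, v]["sign"] = "+" if idx < 220 else "-"
        summ = topology(g)
        assert summ.graph_density == pytest.approx(437 / 4950)
        assert summ.positive_edge_fraction == pytest.approx(220 / 437)
        assert summ.positive_edge_fraction + summ.negative_edge_fraction == pytest.approx(1)

    def test_empty_graph_fraction_convention(self):
        import networkx as nx

        g = nx.empty_graph(3)
        assert topology(g).positive_edge_fraction == 0.0


class TestPerGroupNetworks:
    def _dataset(self, rng, shift=False):
        from rhizonet import SampleMetadata

        n = 10
        base = rng.normal(size=(2 * n, 1))
        data = np.abs(base + 0.4 * rng.normal(size=(2 * n, 6))) + 0.1
        df = pd.DataFrame(
            np.round(100 * data).astype(int) + 1,
            index=[f"s{i}" for i in range(2 * n)],
            columns=[f"t{i}" for i in range(6)],
        )
        md = SampleMetadata(
            groups=pd.Series(["A"] * n + ["B"] * n, index=df.index)
        )
        return FeatureTable(df), md

    def test_identical_groups_identical_topology(self, rng):
        table, md = self._dataset(rng)
        half = table.data.iloc[:10]
        both = pd.concat([half, half.set_index(pd.Index([f"s{i+10}" for i in range(10)]))])
        from rhizonet import SampleMetadata

        table2 = FeatureTable(both)
        md2 = SampleMetadata(groups=pd.Series(["A"] * 10 + ["B"] * 10, index=both.index))
        out = per_group_networks(table2, md2, top_n=6, rho_min=0.3, alpha=0.2)
        assert out["A"][1] == out["B"][1]

    def test_small_group_rejected(self, small_table, small_metadata):
        with pytest.raises(ValueError, match="at least 4"):
            per_group_networks(small_table, small_metadata)

    def test_runs_independently_per_group(self, rng):
        table, md = self._dataset(rng)
        out = per_group_networks(table, md, top_n=6, rho_min=0.4, alpha=0.2)
        assert set(out) == {"A", "B"}
        for _, (net, topo) in out.items():
            assert topo.n_nodes == net.number_of_nodes()
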