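import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycolink import (
    CorrelationNetwork,
    abundance_response_screen,
    diversity_response_screen,
    link_regression,
    network_properties,
    sample_subnetwork,
    subnetwork_property_table,
)


def _net(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, r=0.9, q=0.01, sign="+")
    return CorrelationNetwork(g, inoculum="A")


class TestSampleSubnetwork:
    def test_full_sample_reproduces_parent(self):
        net = _net([("a", "b"), ("b", "c"), ("c", "a")])
        sub = sample_subnetwork(net, {"a": 5, "b": 1, "c": 2})
        assert set(sub.graph.edges) == set(net.graph.edges)
        parent_panel = network_properties(net).as_dict()
        sub_panel = network_properties(sub).as_dict()
        for key, val in parent_panel.items():
            assert sub_panel[key] == pytest.approx(val, nan_ok=True)

    def test_absent_otus_give_empty_graph(self):
        net = _net([("a", "b")])
        sub = sample_subnetwork(net, {"a": 0, "b": 0})
        assert sub.graph.number_of_nodes() == 0

    def test_induced_not_path_contracted(self):
        net = _net([("a", "b"), ("b", "c")])
        sub = sample_subnetwork(net, {"a": 3, "b": 0, "c": 4})
        assert sub.graph.number_of_nodes() == 2
        assert sub.graph.number_of_edges() == 0

    def test_monotone_in_sample_support(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(12, 0.4, seed=1)
        g = nx.relabel_nodes(g, {i: f"o{i}" for i in range(12)})
        nx.set_edge_attributes(g, "+", "sign")
        net = CorrelationNetwork(g)
        counts = {f"o{i}": int(rng.integers(0, 2)) for i in range(12)}
        small = sample_subnetwork(net, counts)
        bigger_counts = dict(counts)
        for k in list(bigger_counts)[:6]:
            bigger_counts[k] = bigger_counts[k] + 1
        big = sample_subnetwork(net, bigger_counts)
        assert big.graph.number_of_nodes() >= small.graph.number_of_nodes()
        assert big.graph.number_of_edges() >= small.graph.number_of_edges()


class TestPropertyTable:
    def test_counts_match_independent_recomputation(self, networks, rarefied_root, responses):
        table, _ = rarefied_root
        records = subnetwork_property_table(networks, table, responses)
        assert len(records) == len(
            [
                s
                for s in table.sample_ids
                if table.sample_meta.loc[s, "inoculum"] != "control"
            ]
        )
        # independent recomputation from the edge list, a few samples deep
        for _, row in records.head(8).iterrows():
            sid = row["sample_id"]
            inoc = row["inoculum"]
            present = set(
                table.counts.columns[table.counts.loc[sid].to_numpy() > 0]
            )
            net = networks[inoc]
            nodes = [v for v in net.graph.nodes if v in present]
            edges = [
                (a, b) for a, b in net.graph.edges if a in present and b in present
            ]
            assert row["node"] == len(nodes)
            assert row["edge"] == len(edges)

    def test_never_more_complex_than_parent(self, networks, rarefied_root, responses):
        table, _ = rarefied_root
        records = subnetwork_property_table(networks, table, responses)
        for inoc, grp in records.groupby("inoculum"):
            parent = networks[inoc].graph
            assert (grp["node"] <= parent.number_of_nodes()).all()
            assert (grp["edge"] <= parent.number_of_edges()).all()

    def test_unmatched_sample_raises(self, networks, rarefied_root, responses):
        table, _ = rarefied_root
        broken = responses[responses["pot_id"] != "pot_A_A_1"]
        if "root_A_A_1" not in table.sample_ids:
            pytest.skip("sample discarded by depth filter in this realisation")
        with pytest.raises(ValueError, match="root_A_A_1"):
            subnetwork_property_table(networks, table, broken)


class TestLinkRegression:
    def test_collinear_points(self):
        records = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        fit = link_regression(records, "x", "y")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 1.5 - 0.7 * x + rng.normal(scale=0.5, size=30)
        fit = link_regression(pd.DataFrame({"x": x, "y": y}), "x", "y")
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = np.sum(resid**2) / (len(x) - 2)
        t = slope / np.sqrt(s2 / sxx)
        p = 2 * stats.t.sf(abs(t), len(x) - 2)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.p == pytest.approx(p)

    def test_standardizing_predictor_preserves_r2_and_p(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=25)
        y = 2 * x + rng.normal(size=25)
        records = pd.DataFrame({"x": x, "y": y})
        records["z"] = (x - x.mean()) / x.std(ddof=1)
        a = link_regression(records, "x", "y")
        b = link_regression(records, "z", "y")
        assert a.r2 == pytest.approx(b.r2)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_predictor_raises(self):
        records = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero variance"):
            link_regression(records, "x", "y")


class TestAbundanceScreen:
    def test_affine_relationship_recovered(self, rarefied_root, responses):
        table, _ = rarefied_root
        # inject an OTU whose relative abundance tracks MGR exactly
        counts = table.counts.copy()
        resp = responses.set_index("pot_id")
        lib = counts.sum(axis=1)
        mgr = np.array(
            [
                resp.loc[table.sample_meta.loc[s, "pot_id"], "MGR"]
                for s in counts.index
            ]
        )
        rel = (mgr - mgr.min() + 0.1) / 40
        counts["OTU_spike"] = np.maximum((rel * lib).astype(int), 1)
        from mycolink import OtuTable

        spiked = OtuTable(counts, table.sample_meta, None)
        out = abundance_response_screen(spiked, responses, top_k=len(counts.columns))
        row = out[(out.otu_id == "OTU_spike") & (out.response == "MGR")].iloc[0]
        assert row["r2"] > 0.95
        assert row["q"] < 0.01

    def test_constant_otu_flagged(self, rarefied_root, responses):
        table, _ = rarefied_root
        counts = table.counts.copy()
        counts["OTU_flat"] = 0
        from mycolink import OtuTable

        flat = OtuTable(counts, table.sample_meta, None)
        out = abundance_response_screen(flat, responses, top_k=len(counts.columns))
        assert bool(out[out.otu_id == "OTU_flat"]["zero_variance"].all())

    def test_top_k_one_screens_most_abundant(self, rarefied_root, responses):
        table, _ = rarefied_root
        out = abundance_response_screen(table, responses, top_k=1)
        most_abundant = table.counts.sum(axis=0).idxmax()
        assert set(out["otu_id"]) == {most_abundant}

    def test_top_k_exceeding_otus_rejected(self, rarefied_root, responses):
        table, _ = rarefied_root
        with pytest.raises(ValueError, match="top_k"):
            abundance_response_screen(table, responses, top_k=10**6)


def test_diversity_screen_runs_on_simulated_experiment(rarefied_root, responses):
    from mycolink import alpha_over_rarefactions, bray_curtis

    table, _ = rarefied_root
    alpha = alpha_over_rarefactions(table, depth=5283, reps=10, seed=0)
    dist = bray_curtis(table)
    out = diversity_response_screen(alpha, dist, table, responses)
    assert set(out["predictor"]) <= {"richness", "shannon", "mean_within_group_bc"}
    assert (out["n"] >= 3).all()
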