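"""Disease enrichment, centrality comparisons, hub selection and
hierarchical views."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import random_bipartite_network
from lncsyn import hubs as lhubs
from lncsyn import topology as ltopo
from lncsyn.datatypes import AnnotationSet, network_from_edges


def _simple_net(n_lnc=4, n_mir=4):
    edges = [
        {"lncRNA": f"L{i}", "miRNA": f"M{j}", "sign": 1, "r": 0.5, "p": 0.01,
         "shared_mrnas": ("g1",)}
        for i in range(n_lnc)
        for j in range(n_mir)
        if (i + j) % 2 == 0
    ]
    return network_from_edges(edges)


class TestEnrichment:
    def test_everything_annotated_gives_p_one(self):
        net = _simple_net()
        members = set(net.nodes_of_class("lncRNA"))
        universe = members | {"Lx", "Ly"}
        res = lhubs.enrichment_test(net, universe, universe, "lncRNA")
        assert res.p_hyper == pytest.approx(1.0)

    def test_worked_example(self):
        net = _simple_net(n_lnc=4)
        members = set(net.nodes_of_class("lncRNA"))
        assert len(members) == 4
        universe = members | {f"U{i}" for i in range(6)}  # N = 10
        annotated = set(list(members)) | {"U0"}           # K = 5, k = 4
        res = lhubs.enrichment_test(net, annotated, universe, "lncRNA")
        assert (res.in_network_annotated, res.universe_annotated, res.universe_size) == (4, 5, 10)
        assert res.p_hyper == pytest.approx(5 / 210, rel=1e-9)

    def test_p_decreases_as_labels_concentrate_in_network(self):
        net = _simple_net()
        members = set(net.nodes_of_class("lncRNA"))
        universe = members | {f"U{i}" for i in range(20)}
        diffuse = lhubs.enrichment_test(net, members | {f"U{i}" for i in range(10)}, universe, "lncRNA")
        concentrated = lhubs.enrichment_test(net, members, universe, "lncRNA")
        assert concentrated.p_hyper < diffuse.p_hyper

    def test_empty_class_raises(self):
        net = _simple_net()
        net.graph.remove_nodes_from(net.nodes_of_class("miRNA"))
        with pytest.raises(ValueError):
            lhubs.enrichment_test(net, set(), set(), "miRNA")


class TestCentralityComparison:
    @staticmethod
    def _records(ann_vals, oth_vals):
        rows = [{"node_id": f"a{i}", "degree": v} for i, v in enumerate(ann_vals)]
        rows += [{"node_id": f"o{i}", "degree": v} for i, v in enumerate(oth_vals)]
        return pd.DataFrame(rows), {f"a{i}" for i in range(len(ann_vals))}

    def test_identical_groups_near_half(self):
        recs, ann = self._records([1, 2, 3, 4], [1, 2, 3, 4])
        _, p, _ = lhubs.compare_centrality(recs, ann, "degree")
        assert 0.4 <= p <= 0.65

    def test_complete_separation_exact_p(self):
        recs, ann = self._records([10, 9, 8], [1, 2, 3])
        w, p, med = lhubs.compare_centrality(recs, ann, "degree")
        assert w == 9
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)
        assert med["annotated"] == 9

    def test_matches_exact_enumeration_small_sample(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 1.0, 5)
        y = rng.normal(0.0, 1.0, 5)
        recs, ann = self._records(x, y)
        _, p, _ = lhubs.compare_centrality(recs, ann, "degree")
        # exact one-sided p by enumerating all group assignments of ranks
        pooled = np.concatenate([x, y])
        u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        count = total = 0
        for idx in itertools.combinations(range(10), 5):
            grp = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            u = sum((a > b) + 0.5 * (a == b) for a in grp for b in rest)
            count += u >= u_obs
            total += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_empty_group_raises(self):
        recs, _ = self._records([1, 2], [3, 4])
        with pytest.raises(ValueError):
            lhubs.compare_centrality(recs, set(), "degree")


class TestHubSelection:
    def test_ceiling_rule_on_249_nodes(self):
        pairs = {(i, i % 161) for i in range(88)} | {(j % 88, j) for j in range(161)}
        net = network_from_edges(
            [
                {"lncRNA": f"L{i}", "miRNA": f"M{j}", "sign": 1, "r": 0.5,
                 "p": 0.01, "shared_mrnas": ("g",)}
                for i, j in sorted(pairs)
            ]
        )
        assert net.graph.number_of_nodes() == 249
        hubs = lhubs.select_hubs(net, 0.1)
        assert hubs.n_hubs == 25

    def test_small_network_ceiling(self):
        net = random_bipartite_network(10, 10, 30, seed=1)
        assert lhubs.select_hubs(net, 0.1).n_hubs == 2

    def test_tie_policy_by_id(self):
        net = _simple_net(4, 4)  # regular: all degrees equal
        hubs = lhubs.select_hubs(net, 0.1)
        degrees = dict(net.graph.degree())
        assert len(set(degrees.values())) == 1
        assert hubs.hub_ids == sorted(net.graph.nodes())[: hubs.n_hubs]

    def test_min_hub_degree_dominates_nonhubs_without_boundary_ties(self):
        net = random_bipartite_network(20, 25, 120, seed=8)
        hubs = lhubs.select_hubs(net, 0.1)
        deg = dict(net.graph.degree())
        hub_min = min(deg[h] for h in hubs.hub_ids)
        nonhub_max = max(deg[n] for n in net.graph if n not in set(hubs.hub_ids))
        assert hub_min >= nonhub_max


class TestHubComposition:
    def test_reference_ratios(self):
        hub_ids = [f"L{i}" for i in range(18)] + [f"M{i}" for i in range(7)]
        # a network covering 88 lncRNAs and 161 miRNAs
        pairs = {(i, i % 161) for i in range(88)} | {(j % 88, j) for j in range(161)}
        edges = [
            {"lncRNA": f"L{i}", "miRNA": f"M{j}", "sign": 1, "r": 0.5,
             "p": 0.01, "shared_mrnas": ("g",)}
            for i, j in sorted(pairs)
        ]
        net = network_from_edges(edges)
        assert len(net.nodes_of_class("lncRNA")) == 88
        assert len(net.nodes_of_class("miRNA")) == 161
        hubset = lhubs.HubSet(hub_ids=hub_ids, top_frac=0.1, n_hubs=25,
                              per_class={"lncRNA": 18, "miRNA": 7})
        comp = lhubs.hub_composition(hubset, net).set_index("rna_class")
        assert comp.loc["lncRNA", "hub_pct"] == 20
        assert comp.loc["miRNA", "hub_pct"] == 4

    def test_no_hubs_of_class_is_zero_percent(self):
        net = _simple_net()
        hubset = lhubs.HubSet(hub_ids=["L0"], top_frac=0.1, n_hubs=1, per_class={"lncRNA": 1})
        comp = lhubs.hub_composition(hubset, net).set_index("rna_class")
        assert comp.loc["miRNA", "hub_pct"] == 0


class TestHubSubnetwork:
    def test_full_network_as_hubs_is_identity(self):
        net = _simple_net()
        hubset = lhubs.HubSet(hub_ids=list(net.graph.nodes()), top_frac=1.0,
                              n_hubs=net.graph.number_of_nodes())
        sub, isolated = lhubs.hub_subnetwork(net, hubset)
        assert sub.graph.number_of_edges() == net.graph.number_of_edges()
        assert isolated == []

    def test_disconnected_hubs_reported_isolated(self):
        net = _simple_net()
        hubset = lhubs.HubSet(hub_ids=["L0", "M1"], top_frac=0.1, n_hubs=2)
        sub, isolated = lhubs.hub_subnetwork(net, hubset)
        # L0-M1 edge does not exist ((0+1) % 2 != 0)
        assert sub.graph.number_of_edges() == 0
        assert isolated == ["L0", "M1"]

    def test_matches_brute_force_edge_filter(self, pipeline_products):
        net = pipeline_products["network"]
        hubset = lhubs.select_hubs(net, 0.3)
        sub, isolated = lhubs.hub_subnetwork(net, hubset)
        hubs = set(hubset.hub_ids)
        expected = {
            frozenset((u, v)) for u, v in net.graph.edges() if u in hubs and v in hubs
        }
        assert {frozenset(e) for e in sub.graph.edges()} == expected


class TestHierarchicalView:
    def test_planted_module_layers(self, pipeline_products):
        ds = pipeline_products["dataset"]
        net = pipeline_products["network"]
        lnc, mir, _ = ds.truth.pairs[0]
        view = lhubs.build_hierarchical_view(net, lnc, ds.annotation, min_term_count=5)
        assert mir in set(view.mirna_layer["miRNA"])
        # layer 3 equals the module's shared mRNAs (module edges only)
        assert set(view.mrna_layer) <= set().union(*ds.truth.module_mrnas.values())
        assert set(view.mrna_layer) >= set(net.graph.edges[lnc, mir]["shared_mrnas"])
        # the module term annotates every module mRNA, so it survives the filter
        assert any(t.startswith("process_") for t in view.term_layer["term"])

    def test_min_term_count_filters_everything(self, pipeline_products):
        ds = pipeline_products["dataset"]
        net = pipeline_products["network"]
        lnc = ds.truth.pairs[0][0]
        view = lhubs.build_hierarchical_view(net, lnc, ds.annotation, min_term_count=10**6)
        assert view.term_layer.empty

    def test_absent_root_raises(self, pipeline_products):
        net = pipeline_products["network"]
        annotation = AnnotationSet()
        with pytest.raises(KeyError):
            lhubs.build_hierarchical_view(net, "NOT_A_NODE", annotation)

    def test_disease_flags_on_mirna_layer(self, pipeline_products):
        ds = pipeline_products["dataset"]
        net = pipeline_products["network"]
        lnc, mir, _ = ds.truth.pairs[1]
        view = lhubs.build_hierarchical_view(net, lnc, ds.annotation)
        flags = dict(zip(view.mirna_layer["miRNA"], view.mirna_layer["disease"]))
        assert flags[mir]  # planted partners are disease-labelled
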