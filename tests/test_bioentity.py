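import io
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biblionet import bioentity as be

from oracles import (brute_betweenness_centrality, brute_closeness_centrality,
                     brute_degree_centrality)


def make_net(edges, categories=None, nodes=()):
    """Small heterogeneous network; default category 'gene'."""
    categories = categories or {}
    g = nx.Graph()
    for n in nodes:
        g.add_node(n)
    for e in edges:
        u, v, *w = e
        g.add_edge(u, v, weight=w[0] if w else 1)
    for n in g.nodes:
        g.nodes[n]["category"] = categories.get(n, "gene")
        g.nodes[n]["name"] = str(n)
    return g


class TestReadPubtator:
    def test_gene_annotation_mapped(self, pubtator_stream):
        mentions = be.read_pubtator(pubtator_stream)
        gene = next(m for m in mentions if m.category == "gene"
                    and m.pmid == "123")
        assert gene.text == "ACE2" and gene.raw_id == "59272"

    def test_species_dropped_and_malformed_skipped(self, pubtator_stream):
        mentions = be.read_pubtator(pubtator_stream)
        # 9 annotation lines: 1 Species dropped, 1 malformed skipped -> 7
        assert len(mentions) == 7
        assert all(m.category in be.CATEGORIES for m in mentions)

    def test_mutation_types_become_variants(self, pubtator_stream):
        mentions = be.read_pubtator(pubtator_stream)
        variants = [m for m in mentions if m.category == "variant"]
        assert {m.text for m in variants} == {"rs2285666", "G8790A"}


class TestResolveMentions:
    def test_non_human_gene_excluded(self, pubtator_stream, dictionaries):
        mentions = be.read_pubtator(pubtator_stream)
        doc_ents, report = be.resolve_mentions(mentions, *dictionaries)
        ids = {e.entity_id for ents in doc_ents.values() for e in ents}
        assert "59272" in ids and "70008" not in ids
        assert report.raw["gene"] == 2 and report.cleaned["gene"] == 1

    def test_mutation_alias_merges_with_snp(self, pubtator_stream,
                                            dictionaries):
        mentions = be.read_pubtator(pubtator_stream)
        doc_ents, _ = be.resolve_mentions(mentions, *dictionaries)
        # G8790A (doc 124) aliases rs2285666, explicitly mentioned in doc 123
        v123 = {e.entity_id for e in doc_ents["123"]
                if e.category == "variant"}
        v124 = {e.entity_id for e in doc_ents["124"]
                if e.category == "variant"}
        assert v123 == v124 == {"rs2285666"}

    def test_all_mappable_input_keeps_counts(self, dictionaries):
        mentions = [be.Mention("1", "ACE2", "gene", "59272"),
                    be.Mention("1", "COVID-19", "disease", "D000086382")]
        _, report = be.resolve_mentions(mentions, *dictionaries)
        assert report.raw == report.cleaned
        assert report.unique["gene"] == report.unique["disease"] == 1


class TestBuildHeteroNetwork:
    def _entity(self, eid, cat):
        return be.BioEntity(eid, eid, cat)

    def test_repeated_comention_accumulates_weight(self):
        pair = {self._entity("59272", "gene"),
                self._entity("D1", "disease")}
        net = be.build_hetero_network([pair, pair, pair])
        assert net.edges["59272", "D1"]["weight"] == 3

    def test_isolated_entity_retained(self):
        net = be.build_hetero_network([{self._entity("A", "gene")},
                                       {self._entity("B", "chemical"),
                                        self._entity("C", "disease")}])
        assert "A" in net and net.degree("A") == 0

    def test_category_pair_tally_conservation(self):
        docs = [
            {self._entity("g1", "gene"), self._entity("d1", "disease")},
            {self._entity("g1", "gene"), self._entity("g2", "gene")},
            {self._entity("c1", "chemical"), self._entity("d1", "disease"),
             self._entity("rs1", "variant")},
            {self._entity("g2", "gene"), self._entity("rs1", "variant")},
            {self._entity("d1", "disease"), self._entity("d2", "disease")},
            {self._entity("c1", "chemical"), self._entity("c2", "chemical")},
        ]
        net = be.build_hetero_network(docs)
        table = be.category_pair_edge_counts(net)
        assert int(table.to_numpy().sum()) == net.number_of_edges()
        assert table.loc["disease", "gene"] == 1
        assert table.loc["gene", "gene"] == 1


class TestCentralities:
    def test_path_graph_anchors(self):
        net = make_net([("a", "b"), ("b", "c")])
        assert be.degree_centrality(net, "b") == 1.0
        assert be.degree_centrality(net, "a") == 0.5
        assert be.closeness_centrality(net, "b") == 1.0
        assert be.closeness_centrality(net, "a") == pytest.approx(2 / 3)

    def test_star_and_cycle_anchors(self):
        star = make_net([("hub", f"l{i}") for i in range(4)])
        assert be.betweenness_centrality(star, "hub") == pytest.approx(1.0)
        assert be.betweenness_centrality(star, "l0") == 0.0
        assert be.closeness_centrality(star, "hub") == 1.0
        cycle = make_net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        for node in "abcd":
            assert be.betweenness_centrality(cycle, node) == \
                pytest.approx(1 / 6)

    def test_disconnected_closeness_wasserman_faust(self):
        net = make_net([("a", "b"), ("c", "d")])
        for node in "abcd":
            assert be.closeness_centrality(net, node) == pytest.approx(1 / 3)

    def test_isolated_node_zero_closeness(self):
        net = make_net([("a", "b")], nodes=["z"])
        assert be.closeness_centrality(net, "z") == 0.0
        assert be.degree_centrality(net, "z") == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        p = float(rng.uniform(0.1, 0.5))
        g = nx.gnp_random_graph(n, p, seed=seed)
        net = make_net(list(g.edges), nodes=list(g.nodes))
        adj = {u: set(net[u]) for u in net.nodes}
        for mine, oracle in [
            (be.degree_centrality(net), brute_degree_centrality(adj)),
            (be.closeness_centrality(net), brute_closeness_centrality(adj)),
            (be.betweenness_centrality(net), brute_betweenness_centrality(adj)),
        ]:
            for node in adj:
                assert mine[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_small_networks_rejected(self):
        net = make_net([("a", "b")])
        with pytest.raises(ValueError):
            be.betweenness_centrality(net, "a")
        with pytest.raises(ValueError):
            be.degree_centrality(make_net([], nodes=["a"]), "a")


class TestEntropyWeights:
    def test_identical_value_sets_equal_weights(self):
        vals = [0.0, 0.3, 0.7, 1.0]
        w = be.entropy_weights(vals, list(vals), list(vals))
        assert w == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_concentrated_centrality_outweighs_dispersed(self):
        dispersed = [0.9, 1.0, 0.95, 0.95]   # near-uniform proportions
        concentrated = [0.0, 0.0, 0.01, 1.0]  # mass on one node
        w_dc, _, w_bc = be.entropy_weights(dispersed, list(dispersed),
                                           concentrated)
        assert w_bc > w_dc

    def test_degenerate_centrality_gets_zero_weight(self):
        w = be.entropy_weights(None, [0.0, 0.5, 1.0], [0.0, 1.0, 0.2])
        assert w[0] == 0.0
        assert sum(w) == pytest.approx(1.0)

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=10, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one_and_nonnegative(self, values):
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(values))
        w = be.entropy_weights(values, perm, list(reversed(values)))
        assert sum(w) == pytest.approx(1.0)
        assert all(x >= 0 for x in w)

    def test_permutation_invariance(self):
        vals = [0.1, 0.4, 0.9, 0.0, 1.0]
        w1 = be.entropy_weights(vals, vals, vals)
        rev = list(reversed(vals))
        w2 = be.entropy_weights(rev, rev, rev)
        assert w1 == pytest.approx(w2)

    def test_literal_mode_reproduces_printed_formula(self):
        vals = [0.0, 0.5, 1.0]
        n = len(vals)
        h = -sum(x * math.log(x) for x in vals if x > 0) / math.log(n)
        w = be.entropy_weights(vals, vals, vals, mode="literal")
        assert w[0] == pytest.approx((1 - h) / (3 - 3 * h))


class TestCombineAndIR:
    def test_combined_extremes(self):
        weights = (0.5, 0.3, 0.2)
        combined = be.combine_centralities(
            {"top": (1, 1, 1), "bottom": (0, 0, 0), "mid": (1, 0, 0.5)},
            weights)
        assert combined["top"] == pytest.approx(1.0)
        assert combined["bottom"] == 0.0
        assert combined["mid"] == pytest.approx(0.6)

    def test_monotone_in_each_centrality(self):
        weights = (0.2, 0.3, 0.5)
        base = be.combine_centralities({"v": (0.5, 0.5, 0.5)}, weights)["v"]
        for bumped in [(0.6, 0.5, 0.5), (0.5, 0.6, 0.5), (0.5, 0.5, 0.6)]:
            assert be.combine_centralities({"v": bumped}, weights)["v"] >= base

    def _ir_net(self):
        return make_net(
            [("g", "target", 3), ("g", "other", 1), ("g", "chem", 9)],
            categories={"target": "disease", "other": "disease",
                        "chem": "chemical"})

    def test_hand_built_ratio(self):
        net = self._ir_net()
        ir, flag = be.intersection_ratio(net, "g", "target")
        assert ir == pytest.approx(0.75) and not flag

    def test_only_target_edge_gives_one(self):
        net = make_net([("g", "target", 2)],
                       categories={"target": "disease"})
        assert be.intersection_ratio(net, "g", "target") == (1.0, False)

    def test_no_disease_edges_flagged_zero(self):
        net = make_net([("g", "chem", 1)],
                       categories={"chem": "chemical"},
                       nodes=["target"])
        net.nodes["target"]["category"] = "disease"
        assert be.intersection_ratio(net, "g", "target") == (0.0, True)

    def test_scale_invariance(self):
        net = self._ir_net()
        ir1, _ = be.intersection_ratio(net, "g", "target")
        for _, nbr, data in net.edges("g", data=True):
            if net.nodes[nbr]["category"] == "disease":
                data["weight"] *= 7
        ir2, _ = be.intersection_ratio(net, "g", "target")
        assert ir1 == pytest.approx(ir2)

    def test_missing_or_non_disease_target_rejected(self):
        net = self._ir_net()
        with pytest.raises(KeyError):
            be.intersection_ratio(net, "g", "absent")
        with pytest.raises(ValueError):
            be.intersection_ratio(net, "g", "chem")


class TestEmergingMap:
    def _profiles(self, points):
        profiles = []
        for i, (ir, combined) in enumerate(points):
            profiles.append(be.GeneProfile(
                entity=be.BioEntity(str(i), f"G{i}", "gene"),
                dc=0, cc=0, bc=0, combined=combined, ir=ir))
        return profiles

    def test_corner_quadrants(self):
        profiles = self._profiles([(1.0, 1.0), (0.0, 0.0), (1.0, 0.0),
                                   (0.0, 1.0)])
        be.emerging_map(profiles, top_k_highlighted=0)
        assert [p.quadrant for p in profiles] == ["I", "III", "IV", "II"]

    def test_emerging_excludes_highlighted(self):
        profiles = self._profiles([(0.9, 1.0), (1.0, 0.8), (0.0, 0.0)])
        emerging, highlighted = be.emerging_map(profiles,
                                                top_k_highlighted=1)
        assert [p.entity.entity_id for p in highlighted] == ["0"]
        assert [p.entity.entity_id for p in emerging] == ["1"]

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            be.emerging_map(self._profiles([(1, 1)]))


class TestFrequencyTrend:
    def test_mention_count_convention(self, dictionaries):
        from biblionet import corpus as cp
        mesh, genes, snps = dictionaries
        mentions = [be.Mention("1", "ACE2", "gene", "59272")] * 3
        corpus = cp.Corpus([cp.PublicationRecord(
            pmid="1", pub_year=2020, pub_month=5)])
        doc_ents, _ = be.resolve_mentions(mentions, mesh, genes, snps)
        top, series = be.entity_frequency_trend(mentions, corpus,
                                                category="gene")
        assert top[0][1] == 3
        assert series.loc["2020-05", "ACE2"] == 3

    def test_document_count_convention(self, dictionaries):
        from biblionet import corpus as cp
        mesh, genes, snps = dictionaries
        mentions = [be.Mention("1", "ACE2", "gene", "59272")] * 3
        corpus = cp.Corpus([cp.PublicationRecord(
            pmid="1", pub_year=2020, pub_month=5)])
        be.resolve_mentions(mentions, mesh, genes, snps)
        top, _ = be.entity_frequency_trend(mentions, corpus,
                                           category="gene", by="documents")
        assert top[0][1] == 1

    def test_small_category_returns_all(self, dictionaries):
        from biblionet import corpus as cp
        mesh, genes, snps = dictionaries
        mentions = [be.Mention("1", "ACE2", "gene", "59272"),
                    be.Mention("1", "IL6", "gene", "3569")]
        corpus = cp.Corpus([cp.PublicationRecord(
            pmid="1", pub_year=2020, pub_month=1)])
        be.resolve_mentions(mentions, mesh, genes, snps)
        top, _ = be.entity_frequency_trend(mentions, corpus, top_k=10,
                                           category="gene")
        assert len(top) == 2
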