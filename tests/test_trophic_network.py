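import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracles
from trophostab import (
    CATEGORIES,
    NetworkConfig,
    association_proportions,
    bh_adjust,
    build_network,
    classify_edge,
    enumerate_edge_types,
    extract_sample_subnetwork,
    filter_by_occurrence,
    network_properties,
    spearman_with_p,
)
from trophostab.core_io import (
    AssociationNetwork,
    DegenerateInputError,
    ValidationError,
)
from conftest import random_abundance_table


class TestEdgeTaxonomy:
    def test_bacteria_protist_positive_is_cross(self):
        etype = classify_edge("bacteria", "protists", 0.7)
        assert etype.category == "positive-cross"

    def test_bacteria_fungi_negative_is_within(self):
        etype = classify_edge("bacteria", "fungi", -0.65)
        assert etype.category == "negative-within"
        assert etype.sign == "negative"

    def test_enumeration_gives_20_types_in_4_categories(self):
        types = enumerate_edge_types()
        assert len(types) == 20
        assert len({t.label for t in types}) == 20
        by_cat = {c: [t for t in types if t.category == c] for c in CATEGORIES}
        assert set(by_cat) == set(CATEGORIES)
        # 6 within kingdom-pairs and 4 cross kingdom-pairs, each x 2 signs
        assert len(by_cat["positive-within"]) == 6
        assert len(by_cat["negative-within"]) == 6
        assert len(by_cat["positive-cross"]) == 4
        assert len(by_cat["negative-cross"]) == 4

    def test_unknown_kingdom_rejected(self):
        with pytest.raises(ValidationError):
            classify_edge("archaea", "fungi", 0.9)

    def test_pair_order_does_not_matter(self):
        a = classify_edge("nematodes", "bacteria", 0.8)
        b = classify_edge("bacteria", "nematodes", 0.8)
        assert a == b


class TestSpearman:
    def test_perfect_monotone_pair(self):
        rho, p = spearman_with_p([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_rank_formula(self):
        rho, _ = spearman_with_p([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_exhaustive_permutations_match_rank_formula(self):
        """For every permutation of 4 distinct values the statistic equals
        the direct 1 - 6 sum d^2 / (n(n^2-1)) computation."""
        x = [10.0, 20.0, 30.0, 40.0]
        for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0]):
            rho, _ = spearman_with_p(x, perm)
            assert rho == pytest.approx(
                oracles.spearman_rho_no_ties(x, perm), abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 2.0, 5.0, 5.0]
        rho, _ = spearman_with_p(x, y)
        assert rho == pytest.approx(oracles.spearman_rho(x, y), abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_p_close_to_t_approximation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho_t, p_t = spearman_with_p(x, y)
        rho_e, p_e = spearman_with_p(x, y, method="exact")
        assert rho_t == pytest.approx(rho_e)
        assert 0.0 < p_e < 1.0


class TestBH:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_matches_stepup_oracle(self, ps):
        adjusted = bh_adjust(ps)
        assert (adjusted >= np.asarray(ps) - 1e-15).all()
        assert (adjusted <= 1.0 + 1e-15).all()
        assert np.allclose(adjusted, oracles.bh_stepup(ps), atol=1e-12)


class TestOccurrenceFilter:
    def _table_with_occurrence(self, occurrences, n_samples=30):
        rows = []
        for occ in occurrences:
            row = np.zeros(n_samples)
            row[:occ] = 1.0
            rows.append(row)
        abund = pd.DataFrame(rows,
                             index=[f"o{i}" for i in range(len(rows))],
                             columns=[f"s{j}" for j in range(n_samples)])
        kingdoms = pd.Series("bacteria", index=abund.index)
        from trophostab import IntegratedAbundanceTable
        return IntegratedAbundanceTable(abundances=abund / n_samples,
                                        kingdoms=kingdoms)

    def test_threshold_20_of_30(self):
        table = self._table_with_occurrence([19, 20, 30])
        cfg = NetworkConfig(min_occurrence=20)
        kept = filter_by_occurrence(table, cfg)
        assert list(kept.abundances.index) == ["o1", "o2"]

    def test_threshold_zero_is_identity(self):
        table = self._table_with_occurrence([0, 5, 30])
        cfg = NetworkConfig(min_occurrence=0)
        assert filter_by_occurrence(table, cfg).abundances.shape[0] == 3

    def test_nothing_surviving_is_an_error(self):
        table = self._table_with_occurrence([1, 2, 3])
        with pytest.raises(DegenerateInputError):
            filter_by_occurrence(table, NetworkConfig(min_occurrence=25))


class TestBuildNetwork:
    def test_planted_pair_recovered(self, field_study):
        from trophostab import merge_integrated

        truth = field_study.truth
        high = [s for s, lv in truth.resource_levels.items() if lv == "high"]
        merged = merge_integrated(field_study.tables)
        from trophostab import IntegratedAbundanceTable
        arm = IntegratedAbundanceTable(abundances=merged.abundances[high],
                                       kingdoms=merged.kingdoms)
        cfg = NetworkConfig()
        net = build_network(filter_by_occurrence(arm, cfg), cfg)
        planted_cross = {
            frozenset((p["otu_a"], p["otu_b"]))
            for p in truth.planted_pairs
            if p["arm"] == "high" and p["scope"] == "cross"
        }
        found = {frozenset(e) for e in net.graph.edges}
        recovered = len(planted_cross & found) / len(planted_cross)
        assert recovered >= 0.8

    def test_extreme_threshold_empties_network(self):
        table = random_abundance_table(20, 30, seed=5)
        cfg = NetworkConfig(rho_threshold=0.999)
        net = build_network(table, cfg)
        assert net.n_edges == 0

    def test_sign_matches_rho_and_attributes_consistent(self, field_bundle):
        for net in field_bundle.networks.values():
            for u, v, data in net.graph.edges(data=True):
                assert abs(data["rho"]) > 0.6
                assert data["adjusted_p"] < 0.05
                assert data["adjusted_p"] >= data["raw_p"] - 1e-15
                expected = "positive" if data["rho"] > 0 else "negative"
                assert data["sign"] == expected
                etype = classify_edge(net.graph.nodes[u]["kingdom"],
                                      net.graph.nodes[v]["kingdom"],
                                      data["rho"])
                assert data["category"] == etype.category
                assert data["type"] == etype.label

    def test_nodes_restricted_to_connected_otus(self, field_bundle):
        for net in field_bundle.networks.values():
            assert all(d > 0 for _, d in net.graph.degree)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_small_tables(self, seed):
        """Edge-for-edge agreement with an independent implementation
        (explicit average ranks + hand-written step-up BH)."""
        rng = np.random.default_rng(seed)
        n_otus = int(rng.integers(4, 11))
        table = random_abundance_table(n_otus, 30, seed=seed + 1000)
        cfg = NetworkConfig(rho_threshold=0.3, alpha=0.2, min_occurrence=0)
        net = build_network(table, cfg)
        expected = oracles.brute_force_network_edges(
            table.abundances.to_numpy(), cfg.rho_threshold, cfg.alpha)
        otus = list(table.abundances.index)
        expected_edges = {frozenset((otus[i], otus[j])): rho
                          for i, j, rho in expected}
        got_edges = {frozenset((u, v)): d["rho"]
                     for u, v, d in net.graph.edges(data=True)}
        assert set(got_edges) == set(expected_edges)
        for key in got_edges:
            assert got_edges[key] == pytest.approx(expected_edges[key],
                                                   abs=1e-9)


class TestSubnetworks:
    def _simple_net(self):
        g = nx.Graph()
        nodes = {"b1": "bacteria", "b2": "bacteria", "f1": "fungi",
                 "p1": "protists"}
        for n, k in nodes.items():
            g.add_node(n, kingdom=k, trophic_level="basal" if k in
                       ("bacteria", "fungi") else "high")

        def add(u, v, rho):
            etype = classify_edge(nodes[u], nodes[v], rho)
            g.add_edge(u, v, rho=rho, raw_p=0.001, adjusted_p=0.01,
                       sign=etype.sign, type=etype.label,
                       category=etype.category)

        add("b1", "b2", 0.8)
        add("b1", "f1", 0.7)
        add("b2", "f1", -0.9)
        add("b1", "p1", 0.75)
        return AssociationNetwork(graph=g)

    def test_induced_subgraph_on_present_otus(self):
        net = self._simple_net()
        present = pd.Series({"b1": 0.5, "b2": 0.5, "f1": 0.0, "p1": 0.0})
        sub = extract_sample_subnetwork(net, present)
        assert set(sub.graph.nodes) == {"b1", "b2"}
        assert set(map(frozenset, sub.graph.edges)) == {frozenset(("b1", "b2"))}

    def test_all_present_gives_identical_network(self):
        net = self._simple_net()
        present = pd.Series(1.0, index=["b1", "b2", "f1", "p1"])
        sub = extract_sample_subnetwork(net, present)
        assert nx.utils.graphs_equal(sub.graph, net.graph)

    def test_none_present_gives_empty_network(self):
        net = self._simple_net()
        sub = extract_sample_subnetwork(
            net, pd.Series(0.0, index=["b1", "b2", "f1", "p1"]))
        assert sub.n_nodes == 0 and sub.n_edges == 0

    def test_proportions_direct_count(self):
        # 3 within + 1 cross edges
        summary = association_proportions(self._simple_net())
        assert summary.n_links == 4
        assert summary.wta_proportion == pytest.approx(0.75)
        assert summary.cta_proportion == pytest.approx(0.25)
        assert sum(summary.category_proportions.values()) == pytest.approx(1.0)
        assert sum(summary.type_proportions.values()) == pytest.approx(1.0)
        assert (sum(summary.category_counts.values())
                == sum(summary.type_counts.values()) == 4)

    def test_all_basal_subnetwork_has_zero_cta(self):
        net = self._simple_net()
        present = pd.Series({"b1": 1.0, "b2": 1.0, "f1": 1.0, "p1": 0.0})
        summary = association_proportions(extract_sample_subnetwork(net,
                                                                    present))
        assert summary.cta_proportion == 0.0

    def test_empty_subnetwork_proportions_missing(self):
        summary = association_proportions(AssociationNetwork(graph=nx.Graph()))
        assert summary.n_links == 0
        assert all(np.isnan(v) for v in summary.category_proportions.values())


class TestNetworkProperties:
    def _net_from_edges(self, edges):
        g = nx.Graph()
        for u, v in edges:
            for n in (u, v):
                g.add_node(n, kingdom="bacteria", trophic_level="basal")
            g.add_edge(u, v, rho=0.9, raw_p=0.0, adjusted_p=0.0,
                       sign="positive", type="bacteria-bacteria:positive",
                       category="positive-within")
        return AssociationNetwork(graph=g)

    def test_triangle(self):
        props = network_properties(self._net_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c")]))
        assert props["density"] == pytest.approx(1.0)
        assert props["mean_degree"] == pytest.approx(2.0)
        assert props["clustering"] == pytest.approx(1.0)
        assert props["avg_path_length_lcc"] == pytest.approx(1.0)

    def test_path_of_three(self):
        props = network_properties(self._net_from_edges(
            [("a", "b"), ("b", "c")]))
        assert props["density"] == pytest.approx(2.0 / 3.0)
        assert props["clustering"] == pytest.approx(0.0)
        assert props["avg_path_length_lcc"] == pytest.approx(4.0 / 3.0)

    def test_empty_graph(self):
        props = network_properties(AssociationNetwork(graph=nx.Graph()))
        assert props["n_nodes"] == 0 and props["n_links"] == 0
        assert props["density"] == 0.0
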