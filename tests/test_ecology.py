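"""Productivity index closed forms and flagging, bipartite network
construction, conservation and the presentation filter (against a
brute-force oracle)."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from marshcaz import ecology
from marshcaz.ecology import (
    build_network,
    filter_network,
    flag_productive,
    network_tables,
    productivity_index,
    productivity_table,
)
from marshcaz.errors import ParameterError


def contrib(rows):
    return pd.DataFrame(rows, columns=["taxon", "cazyme_family", "week",
                                       "sum_mean_mol_pct"])


class TestProductivityIndex:
    def test_equal_output_and_abundance_is_zero(self):
        assert productivity_index(5.0, 5.0) == 0.0

    def test_twofold_is_log10_two(self):
        assert productivity_index(2.0, 1.0) == pytest.approx(math.log10(2), abs=1e-12)

    def test_tenth_is_minus_one(self):
        assert productivity_index(0.5, 5.0) == pytest.approx(-1.0)

    def test_scale_invariance(self):
        assert productivity_index(3.0, 1.5) == pytest.approx(
            productivity_index(30.0, 15.0), abs=1e-12)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ParameterError):
            productivity_index(0.0, 1.0)
        with pytest.raises(ParameterError):
            productivity_index(1.0, 0.0)


class TestFlagProductive:
    def make_records(self, series):
        rows = []
        for taxon, values in series.items():
            for week, idx in enumerate(values, start=1):
                rows.append({"taxon": taxon, "week": week, "index": idx,
                             "sum_mean_mol_pct": 1.0, "abundance": 1.0})
        return pd.DataFrame(rows)

    def test_exactly_threshold_never_flags(self):
        records = self.make_records({"t": [0.3, 0.3, 0.3, 0.3]})
        assert flag_productive(records) == set()

    def test_single_exceedance_flags(self):
        records = self.make_records({"t": [0.0, 0.31, 0.1, -0.2]})
        assert flag_productive(records) == {"t"}

    def test_na_index_ignored(self):
        records = self.make_records({"t": [np.nan, 0.2]})
        assert flag_productive(records) == set()

    def test_taxa_absent_from_profile_get_no_index(self):
        contribs = pd.DataFrame({
            "taxon": ["seen", "unseen"], "week": [1, 1],
            "sum_mean_mol_pct": [5.0, 5.0],
        })
        abund = pd.DataFrame({"taxon": ["seen"], "week": [1], "abundance": [5.0]})
        table = productivity_table(contribs, abund)
        unseen = table[table["taxon"] == "unseen"].iloc[0]
        assert np.isnan(unseen["index"])
        assert unseen["na_reason"] == "not in community profile"
        assert flag_productive(table) == set()


class TestBuildNetwork:
    def test_single_pair(self):
        net = build_network(contrib([("T", "GH5", 1, 4.0)]))
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 1
        assert net.nodes[("taxon", "T")]["weight"] == pytest.approx(4.0)
        assert net.nodes[("cazyme", "GH5")]["weight"] == pytest.approx(4.0)
        assert net.edges[("taxon", "T"), ("cazyme", "GH5")]["weight"] == pytest.approx(4.0)

    def test_additivity_three_to_one(self):
        net = build_network(contrib([("T", "GH5", 1, 3.0), ("T", "CE1", 1, 1.0)]))
        w_gh = net.edges[("taxon", "T"), ("cazyme", "GH5")]["weight"]
        w_ce = net.edges[("taxon", "T"), ("cazyme", "CE1")]["weight"]
        assert w_gh / w_ce == pytest.approx(3.0)
        assert net.nodes[("taxon", "T")]["weight"] == pytest.approx(w_gh + w_ce)

    def test_time_averaging_with_implicit_zeros(self):
        rows = [("T", "GH5", 1, 8.0)] + [("T", "CE1", w, 1.0) for w in (1, 3, 5, 10)]
        net = build_network(contrib(rows))
        # GH5 present at one of four time points: node weight w/4
        assert net.nodes[("cazyme", "GH5")]["weight"] == pytest.approx(2.0)

    def test_family_nodes_carry_class_label(self):
        net = build_network(contrib([("T", "CBM44", 1, 1.0)]))
        assert net.nodes[("cazyme", "CBM44")]["cazy_class"] == "CBM"

    def test_empty_contributions_empty_network(self):
        assert build_network(contrib([])).number_of_nodes() == 0

    def test_edge_sums_equal_taxon_weights_prefilter(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"T{rng.integers(5)}", f"GH{rng.integers(1, 20)}",
             int(rng.choice([1, 3, 5, 10])), float(rng.uniform(0.001, 5)))
            for _ in range(200)
        ]
        net = build_network(contrib(rows))
        for n, d in net.nodes(data=True):
            if d["bipartite"] != "taxon":
                continue
            edge_sum = sum(w["weight"] for _, _, w in net.edges(n, data=True))
            assert edge_sum == pytest.approx(d["weight"], abs=1e-9)


def filter_oracle(net, taxon_min, taxon_max_edges, cazyme_min):
    """Brute-force re-scan: drop weak CAZyme nodes, then taxa that are
    BOTH light and poorly connected (degree counted after the first cut)."""
    keep_caz = {n for n, d in net.nodes(data=True)
                if d.get("bipartite") == "cazyme" and d["weight"] >= cazyme_min}
    taxa = {n for n, d in net.nodes(data=True) if d.get("bipartite") == "taxon"}
    keep_tax = set()
    for t in taxa:
        degree = sum(1 for nb in net.neighbors(t) if nb in keep_caz)
        light = net.nodes[t]["weight"] < taxon_min
        if not (light and degree <= taxon_max_edges):
            keep_tax.add(t)
    keep = keep_caz | keep_tax
    edges = {frozenset((u, v)) for u, v in net.edges if u in keep and v in keep}
    return keep, edges


class TestFilterNetwork:
    def heavy_families(self, n, weight=1.0):
        return [("anchor", f"GH{i}", 1, weight) for i in range(n)]

    def test_light_but_connected_taxon_retained(self):
        # weight 0.024 < 0.025 but degree 6 > 5: the rule is conjunctive
        rows = [("T", f"GH{i}", 1, 0.004) for i in range(6)]
        net = build_network(contrib(rows))
        filtered = filter_network(net)
        assert ("taxon", "T") in filtered
        assert net.nodes[("taxon", "T")]["weight"] == pytest.approx(0.024)

    def test_boundary_weight_taxon_retained(self):
        # weight exactly 0.025 with low degree: strict < keeps it
        net = build_network(contrib([("T", "GH1", 1, 0.025)]))
        assert ("taxon", "T") in filter_network(net)

    def test_light_and_sparse_taxon_removed(self):
        net = build_network(contrib([("T", "GH1", 1, 0.004),
                                     ("anchor", "GH1", 1, 1.0)]))
        filtered = filter_network(net)
        assert ("taxon", "T") not in filtered and ("taxon", "anchor") in filtered

    def test_weak_cazyme_node_removed(self):
        net = build_network(contrib([("T", "GH1", 1, 1.0e-3),
                                     ("T", "GH2", 1, 1.0)]))
        filtered = filter_network(net)
        assert ("cazyme", "GH1") not in filtered
        assert ("cazyme", "GH2") in filtered

    def test_degree_evaluated_after_cazyme_removal(self):
        # taxon with 6 edges, but 2 lead to filtered CAZyme nodes: the
        # post-removal degree 4 <= 5 plus low weight removes the taxon
        rows = [("T", f"GH{i}", 1, 0.003) for i in range(4)]
        rows += [("T", f"PL{i}", 1, 1.0e-4) for i in range(2)]
        net = build_network(contrib(rows))
        assert net.degree(("taxon", "T")) == 6
        assert ("taxon", "T") not in filter_network(net)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        rows = [(f"T{rng.integers(8)}", f"GH{rng.integers(1, 15)}", 1,
                 float(10 ** rng.uniform(-4, 0.5))) for _ in range(80)]
        net = build_network(contrib(rows))
        once = filter_network(net)
        twice = filter_network(once)
        assert set(once.nodes) == set(twice.nodes)
        assert set(map(frozenset, once.edges)) == set(map(frozenset, twice.edges))

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        for seed in range(60):
            rng = np.random.default_rng(seed)
            rows = [
                (f"T{rng.integers(10)}", f"GH{rng.integers(1, 25)}", 1,
                 float(10 ** rng.uniform(-4.5, 0.5)))
                for _ in range(int(rng.integers(5, 60)))
            ]
            net = build_network(contrib(rows))
            got = filter_network(net)
            keep, edges = filter_oracle(net, 0.025, 5, 1.25e-3)
            assert set(got.nodes) == keep
            assert set(map(frozenset, got.edges)) == edges


class TestNetworkTables:
    def test_tables_mirror_graph(self):
        net = build_network(contrib([("T", "GH5", 1, 2.0), ("U", "GH5", 1, 1.0)]))
        nodes, edges = network_tables(net)
        assert len(nodes) == 3 and len(edges) == 2
        assert set(nodes["kind"]) == {"taxon", "cazyme"}
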