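"""LD graph construction, components, and dense-subgraph signatures."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ncxtalk import ld
from ncxtalk.errors import ConfigurationError


def dense_subsets_oracle(graph, threshold, min_size):
    """Exhaustive reference: all inclusion-maximal qualifying vertex sets."""
    nodes = sorted(graph.nodes)
    edges = {frozenset(e) for e in graph.edges}
    qualifying = []
    for size in range(min_size, len(nodes) + 1):
        for subset in combinations(nodes, size):
            n_edges = sum(
                1 for pair in combinations(subset, 2) if frozenset(pair) in edges
            )
            # same density convention as the implementation: the quotient
            # form keeps exact boundaries (e.g. 24/30 == 0.8) exact
            if 2 * n_edges / (size * (size - 1)) >= threshold:
                qualifying.append(frozenset(subset))
    return {
        s for s in qualifying if not any(s < t for t in qualifying)
    }


def _pairs(rows):
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "chrom", "dprime", "r2", "pval"])


class TestBuildSnpGraph:
    SNPS = {"s1": "1", "s2": "1", "s3": "2"}

    def test_edge_requires_both_thresholds(self):
        g = ld.build_snp_graph(self.SNPS, _pairs([("s1", "s2", "1", 0.9, 0.8, 1e-6)]))
        assert g.has_edge("s1", "s2")

    def test_dprime_boundary_is_strict(self):
        g = ld.build_snp_graph(self.SNPS, _pairs([("s1", "s2", "1", 0.7, 0.8, 1e-6)]))
        assert g.number_of_edges() == 0

    def test_pvalue_boundary_is_strict(self):
        g = ld.build_snp_graph(self.SNPS, _pairs([("s1", "s2", "1", 0.9, 0.8, 1e-4)]))
        assert g.number_of_edges() == 0

    def test_cross_chromosome_pair_rejected(self):
        g = ld.build_snp_graph(self.SNPS, _pairs([("s1", "s3", "1", 0.99, 0.9, 1e-9)]))
        assert g.number_of_edges() == 0

    def test_unknown_node_rejected(self):
        g = ld.build_snp_graph(self.SNPS, _pairs([("s1", "sX", "1", 0.99, 0.9, 1e-9)]))
        assert g.number_of_edges() == 0

    def test_edge_count_matches_predicate_scan(self, rng):
        snps = {f"v{i}": "1" for i in range(30)}
        rows = []
        for _ in range(50):
            a, b = rng.choice(30, size=2, replace=False)
            rows.append(
                (f"v{a}", f"v{b}", "1", rng.uniform(0.4, 1.0), 0.5, 10 ** rng.uniform(-8, -2))
            )
        df = _pairs(rows)
        expected = df[(df.dprime > 0.7) & (df.pval < 1e-4)]
        expected_edges = {frozenset((r.snp_a, r.snp_b)) for r in expected.itertuples()}
        g = ld.build_snp_graph(snps, df)
        assert {frozenset(e) for e in g.edges} == expected_edges


class TestComponents:
    def test_two_triangles(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
        comps = ld.connected_components(g)
        assert [len(c) for c in comps] == [3, 3]
        assert comps[0] == {"a", "b", "c"}  # ordered by smallest member on ties

    def test_isolated_nodes_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        assert [len(c) for c in ld.connected_components(g)] == [1] * 5

    def test_planted_blocks_recovered(self, synthetic_bundle):
        outdir, truth = synthetic_bundle
        snps = {s: "19" if b < 2 else "6" for s, b in truth["block_map"].items()}
        snps.update({s: "6" for s in truth["satellites"]})
        graph = ld.build_snp_graph(snps, ld.load_ld_table(outdir / "ld_pairs.tsv"))
        comps = ld.connected_components(graph)
        blocks = {}
        for snp, b in truth["block_map"].items():
            blocks.setdefault(b, set()).add(snp)
        non_singletons = [c for c in comps if len(c) > 1]
        assert sorted(map(sorted, non_singletons)) == sorted(
            map(sorted, blocks.values())
        )


class TestDenseSubgraphs:
    def test_complete_graph_is_single_maximal_set(self):
        k5 = nx.complete_graph(5)
        result = ld.enumerate_dense_subgraphs(k5, 0.9, 2)
        assert result == [frozenset(range(5))]

    def test_sparse_path_yields_nothing(self):
        path = nx.path_graph(6)
        assert ld.enumerate_dense_subgraphs(path, 0.9, 3) == []

    def test_component_below_min_size_yields_nothing(self):
        assert ld.enumerate_dense_subgraphs(nx.complete_graph(2), 0.8, 3) == []

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ld.enumerate_dense_subgraphs(nx.complete_graph(3), 0.8, 1)
        with pytest.raises(ConfigurationError):
            ld.enumerate_dense_subgraphs(nx.complete_graph(3), 1.5, 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        g = nx.gnp_random_graph(n, rng.uniform(0.3, 0.9), seed=seed)
        result = ld.enumerate_dense_subgraphs(g, 0.8, 3)
        assert set(result) == dense_subsets_oracle(g, 0.8, 3)

    @pytest.mark.parametrize("threshold", [0.5, 0.7, 0.85])
    def test_raising_threshold_never_enlarges(self, threshold):
        g = nx.gnp_random_graph(12, 0.6, seed=3)
        low = ld.enumerate_dense_subgraphs(g, threshold, 3)
        high = ld.enumerate_dense_subgraphs(g, min(1.0, threshold + 0.1), 3)
        # every tighter maximal set qualifies at the looser bar, hence sits
        # inside some looser maximal set; the largest set can only shrink
        for h in high:
            assert any(h <= l for l in low)
        if high:
            assert max(map(len, high)) <= max(map(len, low))

    def test_greedy_route_recovers_planted_blocks(self):
        rng = np.random.default_rng(5)
        g = nx.Graph()
        blocks = [[f"b{b}_{i}" for i in range(20 + 4 * b)] for b in range(2)]
        for members in blocks:
            for i, j in combinations(range(len(members)), 2):
                if j == i + 1 or rng.uniform() < 0.95:
                    g.add_edge(members[i], members[j])
        found = ld.enumerate_dense_subgraphs(g.subgraph(blocks[0]), 0.8, 4)
        best = max(
            len(set(blocks[0]) & s) / len(set(blocks[0]) | s) for s in found
        )
        assert best >= 0.9


class TestSignatures:
    @pytest.mark.parametrize(
        "size,expected",
        [(40, 8), (43, 9), (84, 17), (10, 2), (5, 2)],
    )
    def test_min_size_ceiling(self, size, expected):
        assert ld.min_signature_size(size, 0.2, "ceil") == expected

    def test_min_size_floor_alternative(self):
        assert ld.min_signature_size(84, 0.2, "floor") == 16
        assert ld.min_signature_size(43, 0.2, "floor") == 8

    def test_clique_component_gives_one_full_signature(self):
        g = nx.relabel_nodes(nx.complete_graph(10), lambda i: f"n{i}")
        comps = ld.connected_components(g)
        sigs = ld.extract_signatures(comps, g)
        assert len(sigs) == 1
        assert sigs[0].signature_id == "A"
        assert sigs[0].members == frozenset(g.nodes)
        assert sigs[0].density == 1.0

    def test_signatures_satisfy_their_constraints(self, synthetic_bundle):
        outdir, truth = synthetic_bundle
        snps = {s: "19" if truth["block_map"].get(s, 9) < 2 else "6" for s in truth["planted_shared"]}
        graph = ld.build_snp_graph(snps, ld.load_ld_table(outdir / "ld_pairs.tsv"))
        comps = ld.connected_components(graph)
        sigs = ld.extract_signatures(comps, graph)
        for sig in sigs:
            comp = comps[sig.component_id]
            assert sig.members <= comp
            assert ld.density(graph, sig.members) >= 0.8
            assert sig.size >= ld.min_signature_size(len(comp))

    def test_unassigned_examples(self):
        sig = ld.Signature("A", 0, frozenset("abc"), 1.0)
        assert ld.unassigned_snps(set("abcde"), [sig]) == {"d", "e"}
        assert ld.unassigned_snps(set("abc"), [sig]) == set()

    def test_satellites_never_join_signatures(self, synthetic_bundle):
        outdir, truth = synthetic_bundle
        snps = {s: "6" for s in truth["planted_shared"]}
        graph = ld.build_snp_graph(snps, ld.load_ld_table(outdir / "ld_pairs.tsv"))
        comps = ld.connected_components(graph)
        sigs = ld.extract_signatures(comps, graph)
        covered = set().union(*(s.members for s in sigs))
        assert set(truth["satellites"]).isdisjoint(covered)


class TestExport:
    def test_empty_graph_round_trip(self, tmp_path):
        ld.export_graph(nx.Graph(), [], tmp_path / "empty")
        g = nx.read_graphml(tmp_path / "empty.graphml")
        assert g.number_of_nodes() == 0

    def test_triangle_with_signature_labels(self, tmp_path):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        nx.set_node_attributes(g, "1", "chrom")
        sig = ld.Signature("A", 0, frozenset("abc"), 1.0)
        ld.export_graph(g, [sig], tmp_path / "tri")
        back = nx.read_graphml(tmp_path / "tri.graphml")
        assert set(back.nodes) == set("abc")
        assert back.number_of_edges() == 3
        assert all(back.nodes[n]["signatures"] == "A" for n in back.nodes)

    def test_round_trip_and_byte_stability(self, tmp_path, rng):
        g = nx.gnp_random_graph(15, 0.4, seed=9)
        g = nx.relabel_nodes(g, lambda i: f"v{i}")
        nx.set_node_attributes(g, "2", "chrom")
        ld.export_graph(g, [], tmp_path / "one")
        ld.export_graph(g, [], tmp_path / "two")
        assert (tmp_path / "one.graphml").read_bytes() == (tmp_path / "two.graphml").read_bytes()
        back = nx.read_graphml(tmp_path / "one.graphml")
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
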