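import networkx as nx
import numpy as np
import pytest

from pathcompendium import path_analysis as pa
from pathcompendium import synthetic_data as sd

from conftest import make_compendium
from oracle_utils import (
    bfs_all_shortest_paths,
    hypergeom_tail_sum,
    random_directed_graph,
    recursive_simple_paths,
)


def _digraph(arcs):
    g = nx.DiGraph()
    g.add_edges_from(arcs)
    return g


class TestDirectedView:
    def test_undirected_annotation_excluded(self):
        compendium = make_compendium(
            [("P", "dbP", {"A", "B"})], [("A", "B", "d1", "undirected", "unsigned", "unknown")]
        )
        graph = pa.directed_view(compendium)
        assert graph.number_of_edges() == 0

    def test_undirected_allowed_gives_both_arcs(self):
        compendium = make_compendium(
            [("P", "dbP", {"A", "B"})], [("A", "B", "d1", "undirected", "unsigned", "unknown")]
        )
        graph = pa.directed_view(compendium, pa.EdgeFilter(directed_only=False))
        assert set(graph.edges) == {("A", "B"), ("B", "A")}

    def test_conflicting_directions_both_arcs(self):
        compendium = make_compendium(
            [("P", "dbP", {"A", "B"})],
            [
                ("A", "B", "d1", "forward", "unsigned", "unknown"),
                ("A", "B", "d2", "reverse", "unsigned", "unknown"),
            ],
        )
        graph = pa.directed_view(compendium)
        assert set(graph.edges) == {("A", "B"), ("B", "A")}

    def test_source_filter(self):
        compendium = make_compendium(
            [("P", "dbP", {"A", "B", "C"})],
            [
                ("A", "B", "d1", "forward", "unsigned", "unknown"),
                ("B", "C", "d2", "forward", "unsigned", "unknown"),
            ],
        )
        graph = pa.directed_view(compendium, pa.EdgeFilter(sources={"d1"}))
        assert set(graph.edges) == {("A", "B")}

    def test_arc_count_tracks_directed_fraction(self):
        for frac, check in ((0.0, lambda n, e: n == 0), (1.0, lambda n, e: n >= e)):
            config = sd.SyntheticConfig(
                n_genes=200,
                pathway_sources=[("dbP", 5)],
                pathway_size_range=(10, 25),
                n_edges_per_source=200,
                directed_fraction=frac,
                seed=0,
            )
            compendium, _ = sd.generate_compendium(config)
            graph = pa.directed_view(compendium)
            assert check(graph.number_of_edges(), compendium.n_edges)

    def test_arc_count_within_binomial_ci(self):
        frac = 0.4
        config = sd.SyntheticConfig(
            n_genes=300,
            pathway_sources=[("dbP", 6)],
            pathway_size_range=(15, 30),
            n_edges_per_source=500,
            directed_fraction=frac,
            seed=1,
        )
        compendium, _ = sd.generate_compendium(config)
        graph = pa.directed_view(compendium)
        n = compendium.n_edges
        mean, sd_ = n * frac, np.sqrt(n * frac * (1 - frac))
        assert abs(graph.number_of_edges() - mean) < 4 * sd_


class TestShortestPaths:
    def test_direct_arc(self):
        length, paths = pa.shortest_paths(_digraph([("S", "T")]), "S", "T")
        assert length == 1
        assert paths == [["S", "T"]]

    def test_diamond(self):
        g = _digraph([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        length, paths = pa.shortest_paths(g, "A", "D")
        assert length == 2
        assert paths == [["A", "B", "D"], ["A", "C", "D"]]

    def test_no_path(self):
        g = _digraph([("A", "B")])
        g.add_node("Z")
        length, paths = pa.shortest_paths(g, "B", "Z")
        assert length is None and paths == []

    def test_missing_node_raises(self):
        with pytest.raises(ValueError):
            pa.shortest_paths(_digraph([("A", "B")]), "A", "Q")

    def test_random_dags_match_bfs_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(5, 31))
            arcs = [(f"N{a}", f"N{b}") for a, b in random_directed_graph(rng, n, 3 * n)]
            g = _digraph(arcs)
            g.add_nodes_from(f"N{i}" for i in range(n))
            adj = {u: sorted(g.successors(u)) for u in g.nodes}
            length, paths = pa.shortest_paths(g, "N0", f"N{n - 1}")
            oracle = bfs_all_shortest_paths(adj, "N0", f"N{n - 1}")
            assert paths == oracle
            if oracle:
                assert length == len(oracle[0]) - 1


class TestEnumeratePaths:
    def test_chain(self):
        g = _digraph([("A", "B"), ("B", "C"), ("C", "D")])
        enum = pa.enumerate_paths(g, pa.PathQuery(source="A", target="D", max_length=3))
        assert enum.total == 1
        assert enum.counts_by_length == {1: 0, 2: 0, 3: 1}

    def test_worked_example_three_paths(self):
        g = _digraph([("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D")])
        enum = pa.enumerate_paths(g, pa.PathQuery(source="A", target="D", max_length=3))
        assert enum.total == 3
        assert enum.counts_by_length == {1: 0, 2: 2, 3: 1}
        assert enum.cumulative_counts == {1: 0, 2: 2, 3: 3}

    def test_query_validation(self):
        g = _digraph([("A", "B")])
        with pytest.raises(ValueError):
            pa.enumerate_paths(g, pa.PathQuery(source="A", target="A"))
        with pytest.raises(ValueError):
            pa.enumerate_paths(g, pa.PathQuery(source="A", target="B", max_length=9))

    def test_truncation_flag(self):
        g = _digraph(
            [(f"L{i}", f"M{j}") for i in range(4) for j in range(4)]
            + [("S", f"L{i}") for i in range(4)]
            + [(f"M{j}", "T") for j in range(4)]
        )
        enum = pa.enumerate_paths(
            g, pa.PathQuery(source="S", target="T", max_length=4, count_ceiling=3)
        )
        assert enum.truncated
        assert enum.total == 3

    def test_matches_recursive_oracle_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            arcs = [(f"N{a}", f"N{b}") for a, b in random_directed_graph(rng, n, 2 * n)]
            g = _digraph(arcs)
            g.add_nodes_from(f"N{i}" for i in range(n))
            adj = {u: sorted(g.successors(u)) for u in g.nodes}
            max_length = int(rng.integers(1, 7))
            enum = pa.enumerate_paths(
                g, pa.PathQuery(source="N0", target=f"N{n - 1}", max_length=max_length)
            )
            oracle = recursive_simple_paths(adj, "N0", f"N{n - 1}", max_length)
            by_len: dict[int, int] = {}
            for p in oracle:
                by_len[len(p) - 1] = by_len.get(len(p) - 1, 0) + 1
            for length in range(1, max_length + 1):
                assert enum.counts_by_length[length] == by_len.get(length, 0)

    def test_cumulative_counts_bound_shortest(self):
        g = _digraph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("B", "D")])
        enum = pa.enumerate_paths(g, pa.PathQuery(source="A", target="D", max_length=4))
        cum = list(enum.cumulative_counts.values())
        assert all(b >= a for a, b in zip(cum, cum[1:]))
        assert enum.cumulative_counts[enum.shortest_length] >= len(enum.shortest_paths) > 0


class TestThroughFraction:
    def test_unique_out_neighbor_gives_one(self):
        g = _digraph([("S", "R"), ("R", "T"), ("R", "U"), ("U", "T")])
        frac = pa.through_fraction(
            g, pa.PathQuery(source="S", target="T", max_length=4, required_node="R")
        )
        assert frac == 1.0

    def test_zero_paths_undefined(self):
        g = _digraph([("S", "A")])
        g.add_nodes_from(["T", "R"])
        frac = pa.through_fraction(
            g, pa.PathQuery(source="S", target="T", max_length=4, required_node="R")
        )
        assert frac is None

    def test_counts_any_position_by_default(self):
        g = _digraph([("S", "A"), ("A", "R"), ("R", "T"), ("S", "T")])
        frac = pa.through_fraction(
            g, pa.PathQuery(source="S", target="T", max_length=3, required_node="R")
        )
        assert frac == pytest.approx(0.5)

    def test_first_hop_flag(self):
        g = _digraph([("S", "R"), ("R", "T"), ("S", "A"), ("A", "R"), ("A", "T")])
        any_pos = pa.through_fraction(
            g, pa.PathQuery(source="S", target="T", max_length=3, required_node="R")
        )
        first_hop = pa.through_fraction(
            g,
            pa.PathQuery(
                source="S", target="T", max_length=3, required_node="R", first_hop_only=True
            ),
        )
        assert any_pos == pytest.approx(2 / 3)
        assert first_hop == pytest.approx(1 / 3)

    def test_planted_scaffold_recovery(self):
        config = sd.SyntheticConfig(
            scaffold=sd.ScaffoldSpec(chain=[f"S{i}" for i in range(8)], n_bypass=4),
            seed=5,
        )
        compendium, truth = sd.generate_scaffold_network(config)
        graph = pa.directed_view(compendium)
        frac = pa.through_fraction(
            graph,
            pa.PathQuery(source="S0", target="S7", max_length=8, required_node="S1"),
        )
        # the chain path goes through S1; each bypass edge to S_j yields one
        # bypass path S0 -> S_j -> ... -> S7 avoiding S1
        n_paths = 1 + len(truth.bypass_edges)
        assert frac == pytest.approx(1 / n_paths)


class TestExpandScaffold:
    def test_no_candidates_empty(self):
        g = _digraph([("A", "B"), ("B", "C")])
        expansion = pa.expand_scaffold(g, ["A", "B", "C"])
        assert expansion.links == [] and expansion.genes == []

    def test_classification(self):
        assert pa.classify_detour(0, 1) == "parallel"
        assert pa.classify_detour(0, 2) == "feed-forward"
        assert pa.classify_detour(3, 1) == "feed-back"
        assert pa.classify_detour(2, 2 + 1) == "parallel"

    def test_planted_intermediates_with_classes(self):
        config = sd.SyntheticConfig(
            scaffold=sd.ScaffoldSpec(chain=[f"S{i}" for i in range(7)], n_intermediates=3),
            seed=6,
        )
        compendium, truth = sd.generate_scaffold_network(config)
        graph = pa.directed_view(compendium)
        expansion = pa.expand_scaffold(graph, truth.scaffold_nodes)
        assert sorted(expansion.genes) == sorted(x for x, _, _ in truth.intermediates)
        chain_pos = {g: i for i, g in enumerate(truth.scaffold_nodes)}
        expected = {
            (x, s_i, s_j, pa.classify_detour(chain_pos[s_i], chain_pos[s_j]))
            for x, s_i, s_j in truth.intermediates
        }
        assert expected <= set(expansion.links)

    def test_distinct_genes_counted_once(self):
        g = _digraph([("A", "X"), ("X", "B"), ("B", "X"), ("X", "C")])
        expansion = pa.expand_scaffold(g, ["A", "B", "C"])
        assert expansion.genes == ["X"]
        assert len(expansion.links) >= 2

    def test_missing_scaffold_gene_raises(self):
        with pytest.raises(ValueError, match="missing"):
            pa.expand_scaffold(_digraph([("A", "B")]), ["A", "B", "Q"])


class TestScaffoldEdgeEnrichment:
    def _weighted_compendium(self, n_background=100, scaffold_sources=4):
        chain = [f"S{i}" for i in range(5)]
        genes = set(chain) | {f"B{i:03d}" for i in range(n_background + 1)}
        edge_specs = []
        dbs = [f"d{k}" for k in range(scaffold_sources)]
        for a, b in zip(chain, chain[1:]):
            for db in dbs:
                edge_specs.append((a, b, db, "forward", "unsigned", "unknown"))
        for i in range(n_background):
            edge_specs.append((f"B{i:03d}", f"B{i + 1:03d}", "d0"))
        return make_compendium([("P", "dbP", genes)], edge_specs), chain

    def test_all_high_weight_p_one(self):
        compendium, chain = self._weighted_compendium()
        p, weights = pa.scaffold_edge_enrichment(compendium, chain, high_weight_threshold=1)
        assert p == pytest.approx(1.0)
        assert len(weights) == len(chain) - 1

    def test_matches_tail_sum_oracle(self):
        compendium, chain = self._weighted_compendium()
        thresh = 4
        p, weights = pa.scaffold_edge_enrichment(compendium, chain, thresh)
        population = [e.edge_weight for e in compendium.edges.values()]
        N = len(population)
        R = sum(1 for w in population if w >= thresh)
        r = sum(1 for w in weights if w >= thresh)
        assert p == pytest.approx(hypergeom_tail_sum(N, R, len(weights), r), rel=1e-10)

    def test_large_population_tail_sum_frozen(self):
        # 7 successes in a sample of 7, 10% success rate, population 63,276
        from scipy.stats import hypergeom

        p = float(hypergeom.sf(6, 63276, 6328, 7))
        assert p == pytest.approx(9.974578983252914e-08, rel=1e-9)
        assert p == pytest.approx(hypergeom_tail_sum(63276, 6328, 7, 7), rel=1e-9)

    def test_missing_scaffold_edge_raises(self):
        compendium, chain = self._weighted_compendium()
        with pytest.raises(ValueError, match="missing"):
            pa.scaffold_edge_enrichment(compendium, chain + ["B000"], 1)


LIGAND_QUERIES = [
    ("TGFB1", "SMAD4"),
    ("TNF", "NFKB1"),
    ("WNT", "GSK3B"),
]


@pytest.mark.parametrize("ligand,sentinel", LIGAND_QUERIES)
def test_ligand_generic_pipeline_smoke(ligand, sentinel):
    chain = [ligand, "RCPT", "ADAP", "KIN1", "KIN2", sentinel]
    config = sd.SyntheticConfig(
        scaffold=sd.ScaffoldSpec(chain=chain, n_bypass=2, n_intermediates=2), seed=11
    )
    compendium, truth = sd.generate_scaffold_network(config)
    graph = pa.directed_view(compendium)
    enum = pa.enumerate_paths(
        graph,
        pa.PathQuery(source=ligand, target=sentinel, max_length=8, required_node="RCPT"),
    )
    assert enum.total >= 1
    assert enum.through_fraction is not None
    expansion = pa.expand_scaffold(graph, chain)
    assert sorted(expansion.genes) == sorted(x for x, _, _ in truth.intermediates)
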