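import numpy as np
import pytest

from pathsem.expression_io import ExpressionMatrix
from pathsem.graphs import (
    FamilyMap,
    PathwayGraph,
    annotate_degs,
    extract_perturbation_module,
    merge_pir_superfamilies,
    prune_by_partial_correlation,
    read_pathway_graph,
    write_pathway_graph,
)
from pathsem.simulate import fixture_pathways


def _graph(edges, bidirected=(), name="g"):
    g = PathwayGraph(name=name)
    for u, v, s in edges:
        g.add_edge(u, v, s)
    for a, b in bidirected:
        g.add_bidirected(a, b)
    return g


class TestSifIo:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "g.sif"
        p.write_text("A\tactivation\tB\nB\tinhibition\tC\n")
        g = read_pathway_graph(p)
        assert set(g.nodes) == {"A", "B", "C"}
        assert g.directed_edges == {("A", "B"): 1, ("B", "C"): -1}

    def test_read_covariance(self, tmp_path):
        p = tmp_path / "g.sif"
        p.write_text("A\tcovariance\tB\n")
        g = read_pathway_graph(p)
        assert g.bidirected_edges == {frozenset({"A", "B"})}
        assert not g.directed_edges

    def test_unknown_relation_names_line(self, tmp_path):
        p = tmp_path / "g.sif"
        p.write_text("A\tactivation\tB\nA\tbinds\tC\n")
        with pytest.raises(ValueError, match=":2"):
            read_pathway_graph(p)

    def test_round_trip_20_edges(self, tmp_path):
        rng = np.random.default_rng(0)
        g = PathwayGraph(name="big")
        nodes = [f"n{i}" for i in range(15)]
        edges = set()
        while len(edges) < 18:
            u, v = rng.choice(15, 2, replace=False)
            edges.add((nodes[u], nodes[v]))
        for k, (u, v) in enumerate(sorted(edges)):
            g.add_edge(u, v, 1 if k % 3 else -1)
        g.add_bidirected("n0", "n14")
        g.add_bidirected("n1", "n13")
        p = tmp_path / "rt.sif"
        write_pathway_graph(g, p)
        assert read_pathway_graph(p) == g

    def test_isolated_node_round_trip(self, tmp_path):
        g = _graph([("A", "B", 1)])
        g.add_node("LONER")
        p = tmp_path / "iso.sif"
        write_pathway_graph(g, p)
        assert "LONER" in read_pathway_graph(p).nodes

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        nxg = nx.DiGraph()
        nxg.add_edge("A", "B", relation="activation")
        nxg.add_edge("B", "C", relation="inhibition")
        p = tmp_path / "g.graphml"
        nx.write_graphml(nxg, p)
        g = read_pathway_graph(p)
        assert g.directed_edges == {("A", "B"): 1, ("B", "C"): -1}


class TestGraphInvariants:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            _graph([("A", "A", 1)])

    def test_dangling_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            PathwayGraph("g", ["A"], {("A", "B"): 1}, set())


class TestAnnotateDegs:
    def test_disjoint_ids_all_false(self, fixtures):
        g = annotate_degs(fixtures["chain5"].graph, {"X", "Y"})
        assert not any(g.deg_flags.values())

    def test_fcgamma_toy_four_flags(self, fixtures):
        fx = fixtures["fcgamma-toy"]
        g = annotate_degs(fx.graph, fx.deg_ids)
        assert sorted(g.deg_nodes) == sorted(["CRKL", "ARF6", "PLA2G4A", "ARPC4"])

    def test_idempotent(self, fixtures):
        fx = fixtures["fcgamma-toy"]
        once = annotate_degs(fx.graph, fx.deg_ids)
        twice = annotate_degs(once, fx.deg_ids)
        assert once.deg_flags == twice.deg_flags


class TestExtractModule:
    def test_chain_end_degs(self):
        g = _graph([("A", "B", 1), ("B", "C", 1)])
        mod = extract_perturbation_module(g, {"A", "C"})
        assert set(mod.nodes) == {"A", "B", "C"}
        assert set(mod.directed_edges) == {("A", "B"), ("B", "C")}

    def test_diamond_keeps_all_tied_paths(self):
        g = _graph([("A", "B", 1), ("B", "D", 1), ("A", "C", 1), ("C", "D", 1)])
        mod = extract_perturbation_module(g, {"A", "D"})
        assert set(mod.nodes) == {"A", "B", "C", "D"}

    def test_direction_reversed_equivalence(self):
        fwd = _graph([("A", "B", 1), ("B", "C", 1)])
        rev = _graph([("C", "B", 1), ("B", "A", 1)])
        m1 = extract_perturbation_module(fwd, {"A", "C"})
        m2 = extract_perturbation_module(rev, {"A", "C"})
        assert set(m1.nodes) == set(m2.nodes)

    def test_undirected_fallback(self):
        # A and C both feed B: no directed path between them in either direction
        g = _graph([("A", "B", 1), ("C", "B", 1)])
        mod = extract_perturbation_module(g, {"A", "C"})
        assert set(mod.nodes) == {"A", "B", "C"}

    def test_no_deg_error(self):
        g = _graph([("A", "B", 1)])
        with pytest.raises(ValueError, match="no DEG"):
            extract_perturbation_module(g, {"Z"})

    def test_subgraph_invariant(self, fixtures):
        fx = fixtures["fcgamma-toy"]
        mod = extract_perturbation_module(fx.graph, fx.deg_ids)
        assert set(mod.nodes) <= set(fx.graph.nodes)
        assert set(fx.deg_ids) <= set(mod.nodes)
        for e, s in mod.directed_edges.items():
            assert fx.graph.directed_edges[e] == s


class TestMergeSuperfamilies:
    def _matrix_for(self, genes, seed=0, n=20):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            list(genes), [f"s{j}" for j in range(n)], rng.normal(size=(len(genes), n))
        )

    def test_empty_map_is_identity(self):
        g = _graph([("A", "B", 1)])
        m = self._matrix_for(["A", "B"])
        g2, m2 = merge_pir_superfamilies(g, m, FamilyMap({}))
        assert g2 == g
        np.testing.assert_allclose(m2.values, m.values)

    def test_perfectly_correlated_members(self):
        g = _graph([("A", "X1", 1), ("A", "X2", 1)])
        g = annotate_degs(g, {"A"})
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        m = ExpressionMatrix(
            ["A", "X1", "X2"], [f"s{j}" for j in range(20)],
            np.vstack([rng.normal(size=20), base, 3.0 * base + 5.0]),
        )
        g2, m2 = merge_pir_superfamilies(g, m, FamilyMap({"X1": "FAM", "X2": "FAM"}))
        assert "FAM" in g2.nodes and "X1" not in g2.nodes
        zb = (base - base.mean()) / base.std()
        merged = m2.values[m2.gene_ids.index("FAM")]
        np.testing.assert_allclose(merged, zb, atol=1e-10)

    def test_deg_never_merged(self, fixtures):
        fx = fixtures["fcgamma-toy"]
        g = annotate_degs(fx.graph, fx.deg_ids)
        fam = FamilyMap({"ARPC4": "ARPC", "ARPC5": "ARPC"})
        m = self._matrix_for(g.nodes)
        g2, _ = merge_pir_superfamilies(g, m, fam)
        assert "ARPC4" in g2.nodes  # DEG member stays; singleton family not merged
        assert "ARPC5" in g2.nodes

    def test_sign_conflict_error(self):
        g = _graph([("A", "X1", 1), ("A", "X2", -1)])
        m = self._matrix_for(["A", "X1", "X2"])
        with pytest.raises(ValueError, match="sign conflict"):
            merge_pir_superfamilies(g, m, FamilyMap({"X1": "FAM", "X2": "FAM"}))

    def test_node_count_arithmetic(self):
        g = _graph([("A", "X1", 1), ("X1", "X2", 1), ("X2", "B", 1)])
        m = self._matrix_for(["A", "X1", "X2", "B"])
        g2, _ = merge_pir_superfamilies(g, m, FamilyMap({"X1": "F", "X2": "F"}))
        assert len(g2.nodes) == 4 - 2 + 1

    def test_missing_member_error(self):
        g = _graph([("A", "B", 1)])
        m = self._matrix_for(["A"])
        with pytest.raises(ValueError, match="missing"):
            merge_pir_superfamilies(g, m, FamilyMap({}))


class TestPrune:
    def _chain_data(self, seed, n=500, beta=0.8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = beta * x + rng.normal(scale=np.sqrt(1 - beta**2), size=n)
        z = beta * y + rng.normal(scale=np.sqrt(1 - beta**2), size=n)
        return ExpressionMatrix(["X", "Y", "Z"], [f"s{j}" for j in range(n)],
                                np.vstack([x, y, z]))

    def test_strong_edge_kept(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=100)
        m = ExpressionMatrix(["X", "Y"], [f"s{j}" for j in range(100)], np.vstack([x, y]))
        g = _graph([("X", "Y", 1)])
        assert ("X", "Y") in prune_by_partial_correlation(g, m, 0.05).directed_edges

    def test_spurious_edge_pruned(self):
        g = _graph([("X", "Y", 1), ("Y", "Z", 1), ("X", "Z", 1)])
        hits = 0
        for seed in range(30):
            m = self._chain_data(seed)
            pruned = prune_by_partial_correlation(g, m, 0.05)
            ok = (("X", "Z") not in pruned.directed_edges
                  and ("X", "Y") in pruned.directed_edges
                  and ("Y", "Z") in pruned.directed_edges)
            hits += ok
        assert hits >= 27

    def test_alpha_one_is_identity(self):
        g = _graph([("X", "Y", 1), ("Y", "Z", 1), ("X", "Z", 1)])
        m = self._chain_data(3)
        pruned = prune_by_partial_correlation(g, m, alpha=1.0)
        assert pruned.directed_edges == g.directed_edges

    def test_never_adds_edges(self):
        g = _graph([("X", "Y", 1), ("Y", "Z", 1)], bidirected=[("X", "Z")])
        m = self._chain_data(4)
        pruned = prune_by_partial_correlation(g, m, 0.05)
        assert set(pruned.directed_edges) <= set(g.directed_edges)
        assert pruned.bidirected_edges <= g.bidirected_edges

    def test_zero_variance_error(self):
        m = ExpressionMatrix(["X", "Y"], ["a", "b", "c", "d", "e", "f", "g", "h"],
                             np.vstack([np.ones(8), np.arange(8.0)]))
        g = _graph([("X", "Y", 1)])
        with pytest.raises(ValueError, match="zero-variance"):
            prune_by_partial_correlation(g, m, 0.05)

    def test_insufficient_n_error(self):
        rng = np.random.default_rng(5)
        m = ExpressionMatrix(["X", "Y", "Z", "W"], [f"s{j}" for j in range(5)],
                             rng.normal(size=(4, 5)))
        g = _graph([("X", "W", 1), ("Y", "W", 1), ("Z", "W", 1)])
        with pytest.raises(ValueError, match="insufficient"):
            prune_by_partial_correlation(g, m, 0.05, conditioning="full")


class TestFixtures:
    def test_chain5_shape(self, fixtures):
        g = fixtures["chain5"].graph
        assert len(g.nodes) == 5 and len(g.directed_edges) == 4
        assert not g.bidirected_edges

    def test_inhibit_loop(self, fixtures):
        import networkx as nx

        g = fixtures["inhibit-loop"].graph
        assert sum(1 for s in g.directed_edges.values() if s == -1) == 1
        assert not nx.is_directed_acyclic_graph(g.to_networkx())

    def test_fcgamma_size(self, fixtures):
        fx = fixtures["fcgamma-toy"]
        assert len(fx.graph.nodes) == 12
        assert len(fx.deg_ids) == 4

    def test_registry_deterministic(self):
        a = fixture_pathways()
        b = fixture_pathways()
        assert list(a) == list(b)
        assert all(a[k].graph == b[k].graph for k in a)
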