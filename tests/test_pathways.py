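"""Sub-network extraction, contrast comparison, enrichment, heatmap matrix."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import trncontrast as tc
from trncontrast.diffexpr import NOT_DE
from trncontrast.network import TRN


def _trn_from_edges(edges, extra_nodes=(), contrast=("reference", "mutant")):
    g = nx.DiGraph()
    for n in extra_nodes:
        g.add_node(n, de_flag=NOT_DE, is_direct_target=False)
    for u, v in edges:
        g.add_edge(u, v, evidence="motif", rho=0.5, sign="positive")
    for n in g.nodes:
        g.nodes[n].setdefault("de_flag", "up")
        g.nodes[n].setdefault("is_direct_target", False)
        g.nodes[n]["degree"] = g.in_degree(n) + g.out_degree(n)
    return TRN(g, contrast=contrast)


class TestSubTRN:
    def test_seed_with_three_neighbors(self):
        trn = _trn_from_edges([("a", "s"), ("b", "s"), ("s", "c"),
                               ("x", "y")])
        sub = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "toy")
        assert set(sub.nodes) == {"a", "b", "c", "s"}
        assert len(sub.edges) == 3
        assert sub.hub_id == "s"

    def test_pathway_without_de_members_is_empty(self):
        trn = _trn_from_edges([("a", "s")])
        sub = tc.extract_pathway_subtrn(trn, {"s"}, set(), "toy")
        assert sub.n_nodes == 0
        assert sub.hub_id is None

    def test_neighbor_edge_switch(self):
        # a->s, a->b, b->s: a and b are both neighbors of the seed s
        trn = _trn_from_edges([("a", "s"), ("a", "b"), ("b", "s")])
        seed_only = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "toy")
        induced = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "toy",
                                            include_neighbor_edges=True)
        assert ("a", "b") not in seed_only.edges
        assert ("a", "b") in induced.edges
        assert set(seed_only.nodes) == set(induced.nodes)

    def test_matches_bruteforce_neighborhood_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            genes = [f"g{i}" for i in range(20)]
            edges = set()
            while len(edges) < 25:
                u, v = rng.choice(genes, 2, replace=False)
                edges.add((u, v))
            trn = _trn_from_edges(sorted(edges))
            pathway = set(rng.choice(genes, 6, replace=False))
            de = set(rng.choice(genes, 10, replace=False))
            sub = tc.extract_pathway_subtrn(trn, pathway, de, "rand")
            seeds = pathway & de & set(trn.graph.nodes)
            nodes = set(seeds)
            for u, v in edges:
                if u in seeds:
                    nodes.add(v)
                if v in seeds:
                    nodes.add(u)
            assert set(sub.nodes) == nodes
            expected_edges = {(u, v) for u, v in edges
                              if (u in seeds or v in seeds)
                              and u in nodes and v in nodes}
            assert set(sub.edges) == expected_edges
            # sub-network is always contained in its parent
            assert set(sub.nodes) <= set(trn.graph.nodes)
            assert set(sub.edges) <= set(trn.graph.edges)

    def test_hub_tie_breaks_lexicographically(self):
        trn = _trn_from_edges([("a", "s"), ("b", "s"), ("s", "a")])
        sub = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "toy")
        # s has degree 3; a has degree 2; b degree 1
        assert sub.hub_id == "s"
        trn2 = _trn_from_edges([("a", "s"), ("b", "t"), ("t", "x"), ("s", "y")])
        sub2 = tc.extract_pathway_subtrn(trn2, {"s", "t"}, {"s", "t"}, "toy")
        # s and t both have degree 2: lexicographically smallest wins
        assert sub2.hub_id == "s"


class TestMerge:
    def test_single_subtrn_is_identity(self):
        trn = _trn_from_edges([("a", "s"), ("s", "b")])
        sub = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "p1")
        merged = tc.merge_subtrns([sub])
        assert set(merged.graph.nodes) == set(sub.nodes)
        assert set(merged.graph.edges) == set(sub.edges)
        assert merged.graph.nodes["s"]["pathways"] == "p1"

    def test_disjoint_union_counts_add(self):
        trn = _trn_from_edges([("a", "s"), ("x", "t")])
        s1 = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "p1")
        s2 = tc.extract_pathway_subtrn(trn, {"t"}, {"t"}, "p2")
        merged = tc.merge_subtrns([s1, s2])
        assert merged.n_nodes == s1.n_nodes + s2.n_nodes

    def test_overlap_union_and_membership(self):
        trn = _trn_from_edges([("a", "s"), ("a", "t")])
        s1 = tc.extract_pathway_subtrn(trn, {"s"}, {"s"}, "p1")
        s2 = tc.extract_pathway_subtrn(trn, {"t"}, {"t"}, "p2")
        merged = tc.merge_subtrns([s1, s2])
        assert set(merged.graph.nodes) == set(s1.nodes) | set(s2.nodes)
        assert merged.graph.nodes["a"]["pathways"] == "p1;p2"

    def test_mixed_contrasts_rejected(self):
        t1 = _trn_from_edges([("a", "s")], contrast=("reference", "m1"))
        t2 = _trn_from_edges([("a", "s")], contrast=("reference", "m2"))
        s1 = tc.extract_pathway_subtrn(t1, {"s"}, {"s"}, "p1")
        s2 = tc.extract_pathway_subtrn(t2, {"s"}, {"s"}, "p1")
        with pytest.raises(ValueError):
            tc.merge_subtrns([s1, s2])


def _de_from_sets(up, down, contrast):
    genes = sorted(up | down)
    table = pd.DataFrame(
        {"baseMeanA": 1.0, "baseMeanB": 1.0, "log2fc": 0.0, "pvalue": 0.01,
         "padj": 0.01,
         "de_flag": ["up" if g in up else "down" for g in genes]},
        index=genes)
    return tc.DEResult(contrast=contrast, table=table)


class TestCompareContrasts:
    direct = tc.DirectTargetSet("HUB", frozenset({"g1", "g2", "g3"}))

    def test_identical_inputs(self):
        de = _de_from_sets({"g1", "g4"}, {"g2"}, ("reference", "m1"))
        de2 = _de_from_sets({"g1", "g4"}, {"g2"}, ("reference", "m2"))
        trn = _trn_from_edges([("g1", "g4")], contrast=("reference", "m1"))
        cmp_ = tc.compare_contrasts(trn, trn, de, de2, self.direct)
        assert cmp_.specific_fraction_up == 0.0
        assert cmp_.specific_fraction_down == 0.0
        assert cmp_.node_jaccard == 1.0
        assert cmp_.edge_jaccard == 1.0

    def test_disjoint_de_sets(self):
        de_a = _de_from_sets({"g1"}, set(), ("reference", "m1"))
        de_b = _de_from_sets({"g4"}, set(), ("reference", "m2"))
        trn = _trn_from_edges([], extra_nodes=["g1"])
        cmp_ = tc.compare_contrasts(trn, trn, de_a, de_b, self.direct)
        assert cmp_.shared_up == 0
        assert cmp_.specific_fraction_up == 1.0

    def test_ten_gene_toy_hand_counts(self):
        # contrast A: up {g1,g2,g5,g6}, down {g3,g7}
        # contrast B: up {g1,g5},       down {g3,g4,g8}
        de_a = _de_from_sets({"g1", "g2", "g5", "g6"}, {"g3", "g7"},
                             ("reference", "mA"))
        de_b = _de_from_sets({"g1", "g5"}, {"g3", "g4", "g8"},
                             ("reference", "mB"))
        trn_a = _trn_from_edges([("g1", "g2"), ("g5", "g6")],
                                contrast=("reference", "mA"))
        trn_b = _trn_from_edges([("g1", "g5")], contrast=("reference", "mB"))
        cmp_ = tc.compare_contrasts(trn_a, trn_b, de_a, de_b, self.direct)
        assert cmp_.per_contrast["mA"] == {
            "n_up": 4, "n_down": 2, "direct_up": 2, "direct_down": 1,
            "trn_nodes": 4, "trn_edges": 2}
        assert cmp_.per_contrast["mB"] == {
            "n_up": 2, "n_down": 3, "direct_up": 1, "direct_down": 1,
            "trn_nodes": 2, "trn_edges": 1}
        assert cmp_.shared_up == 2          # g1, g5
        assert cmp_.shared_down == 1        # g3
        assert cmp_.specific_fraction_up == pytest.approx(2 / 4)
        assert cmp_.specific_fraction_down == pytest.approx(3 / 4)
        # nodes: A {g1,g2,g5,g6}, B {g1,g5} -> jaccard 2/4
        assert cmp_.node_jaccard == pytest.approx(0.5)
        assert cmp_.edge_jaccard == pytest.approx(0.0)

    def test_symmetric_under_swap(self):
        de_a = _de_from_sets({"g1", "g2"}, {"g3"}, ("reference", "mA"))
        de_b = _de_from_sets({"g1"}, {"g3", "g4"}, ("reference", "mB"))
        trn_a = _trn_from_edges([("g1", "g2")], contrast=("reference", "mA"))
        trn_b = _trn_from_edges([("g1", "g4")], contrast=("reference", "mB"))
        ab = tc.compare_contrasts(trn_a, trn_b, de_a, de_b, self.direct)
        ba = tc.compare_contrasts(trn_b, trn_a, de_b, de_a, self.direct)
        assert ab.per_contrast["mA"] == ba.per_contrast["mA"]
        assert ab.shared_up == ba.shared_up
        assert ab.specific_fraction_up == ba.specific_fraction_up
        assert ab.node_jaccard == ba.node_jaccard

    def test_different_references_rejected(self):
        de_a = _de_from_sets({"g1"}, set(), ("reference", "mA"))
        de_b = _de_from_sets({"g1"}, set(), ("other", "mB"))
        trn = _trn_from_edges([], extra_nodes=["g1"])
        with pytest.raises(ValueError):
            tc.compare_contrasts(trn, trn, de_a, de_b, self.direct)


def _hypergeom_tail_bruteforce(k, N, K, n):
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += (math.comb(K, j) * math.comb(N - K, n - j)) / math.comb(N, n)
    return total


class TestEnrichment:
    def test_empty_gene_list(self):
        sets = tc.PathwayGeneSets.from_lists({"s1": ["a", "b"]})
        assert tc.fisher_enrich([], {"a", "b", "c"}, sets) == []

    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        sets = tc.PathwayGeneSets.from_lists({"hit": universe[:5]})
        rows = tc.fisher_enrich(universe[:5], universe, sets)
        assert rows[0].pvalue == pytest.approx(1 / 15504, rel=1e-12)
        assert rows[0].k == rows[0].K == rows[0].n == 5
        assert rows[0].N == 20

    def test_matches_tail_sum_oracle(self):
        rng = np.random.default_rng(41)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(25):
            members = rng.choice(universe, rng.integers(3, 25), replace=False)
            query = rng.choice(universe, rng.integers(3, 25), replace=False)
            sets = tc.PathwayGeneSets.from_lists({"s": list(members)})
            rows = tc.fisher_enrich(list(query), universe, sets, top_k=5)
            k = len(set(query) & set(members))
            expected = _hypergeom_tail_bruteforce(k, 60, len(members),
                                                  len(query))
            assert rows[0].pvalue == pytest.approx(expected, rel=1e-10)

    def test_pvalue_monotone_in_overlap(self):
        from scipy import stats

        pvals = [float(stats.hypergeom.sf(k - 1, 50, 10, 12))
                 for k in range(0, 11)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_clipping_and_truncation(self, caplog):
        universe = [f"g{i}" for i in range(30)]
        sets = tc.PathwayGeneSets.from_lists(
            {f"s{i}": universe[i:i + 4] for i in range(12)})
        with caplog.at_level("WARNING", logger="trncontrast.pathways"):
            rows = tc.fisher_enrich(universe[:6] + ["alien"], universe, sets,
                                    top_k=10)
        assert len(rows) == 10
        assert any("clipped" in m for m in caplog.messages)
        assert [r.pvalue for r in rows] == sorted(r.pvalue for r in rows)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            tc.fisher_enrich(["a"], [], tc.PathwayGeneSets.from_lists({}))


class TestConditionScaledMatrix:
    design = tc.SampleDesign.from_replicates(
        {"reference": 2, "hypomorph": 2, "null": 2})

    def _em(self, rows, genes):
        return tc.ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=list(self.design.samples)),
            raw=False)

    def test_hand_zscore(self):
        # condition means 2, 4, 6 -> centered (-2, 0, 2), sample sd 2
        em = self._em([[2, 2, 4, 4, 6, 6]], ["g1"])
        out = tc.condition_scaled_matrix(em, self.design, ["g1"])
        assert np.allclose(out.loc["g1"], [-1.0, 0.0, 1.0])
        assert list(out.columns) == ["reference", "hypomorph", "null"]

    def test_flat_row_maps_to_zeros(self):
        em = self._em([[3, 3, 3, 3, 3, 3]], ["g1"])
        out = tc.condition_scaled_matrix(em, self.design, ["g1"])
        assert np.allclose(out.loc["g1"], 0.0)

    def test_scale_invariance(self):
        base = np.array([[2, 2, 4, 4, 6, 6]], dtype=float)
        em1 = self._em(base, ["g1"])
        em2 = self._em(base * 17.5, ["g1"])
        out1 = tc.condition_scaled_matrix(em1, self.design, ["g1"])
        out2 = tc.condition_scaled_matrix(em2, self.design, ["g1"])
        assert np.allclose(out1, out2)

    def test_unknown_gene_raises(self):
        em = self._em([[1, 2, 3, 4, 5, 6]], ["g1"])
        with pytest.raises(KeyError, match="ghost"):
            tc.condition_scaled_matrix(em, self.design, ["ghost"])
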