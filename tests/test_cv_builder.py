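"""Similarity graph, spectral sweep cuts, and fold assignment."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rtamhc.data import Peptide
from rtamhc.graphs import (
    assign_folds,
    build_fold_assignment,
    build_similarity_graph,
    connected_components,
    fiedler_vector,
    laplacian,
    ninemers,
    overlap_report,
    partition_groups,
    shared_ninemers,
    sparsity,
    sweep_cut,
)

from conftest import random_peptide


def two_cliques_with_bridge(n=5):
    g = nx.Graph()
    left = [f"a{i}" for i in range(n)]
    right = [f"b{i}" for i in range(n)]
    g.add_edges_from(itertools.combinations(left, 2))
    g.add_edges_from(itertools.combinations(right, 2))
    g.add_edge(left[0], right[0])
    return g, left, right


def exhaustive_min_sparsity(graph, nodes):
    """Brute-force sparsest cut over all bipartitions (exponential)."""
    best = None
    nodes = list(nodes)
    for r in range(1, len(nodes)):
        for S in itertools.combinations(nodes, r):
            sp = sparsity(graph, S, nodes)
            if best is None or sp < best:
                best = sp
    return best


class TestSharedNinemers:
    def test_identity(self):
        assert shared_ninemers("AAAAAAAAA", "AAAAAAAAA") == {"AAAAAAAAA"}

    def test_sliding_window_enumeration(self):
        assert shared_ninemers("ACDEFGHIKLM", "CDEFGHIKLMN") == {
            "CDEFGHIKL",
            "DEFGHIKLM",
        }

    def test_disjoint(self):
        assert shared_ninemers("ACDEFGHIK", "LMNPQRSTV") == set()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ninemers("ACDEFGHI")


class TestBuildSimilarityGraph:
    def test_dissimilar_peptides_no_edges(self, rng):
        peptides = [
            Peptide(id=f"p{i}", sequence=random_peptide(rng, 12)) for i in range(10)
        ]
        graph = build_similarity_graph(peptides)
        assert graph.number_of_nodes() == 10
        # random 12-mers essentially never share a 9-mer
        assert graph.number_of_edges() == 0

    def test_containment_creates_edge(self):
        peptides = [
            Peptide(id="p0", sequence="ACDEFGHIKL"),
            Peptide(id="p1", sequence="ACDEFGHIKLM"),
        ]
        assert build_similarity_graph(peptides).has_edge("p0", "p1")

    def test_duplicate_ids_rejected(self):
        peptides = [Peptide(id="x", sequence="ACDEFGHIK")] * 2
        with pytest.raises(ValueError):
            build_similarity_graph(peptides)

    def test_matches_all_pairs_oracle(self, rng):
        # family structure ensures plenty of shared 9-mers
        from rtamhc.synthetic import SyntheticSpec, generate_peptides

        spec = SyntheticSpec(n_peptides=200, family_fraction=0.5, seed=21)
        peptides = generate_peptides(spec, np.random.default_rng(21))
        graph = build_similarity_graph(peptides)
        expected = {
            frozenset((a.id, b.id))
            for a, b in itertools.combinations(peptides, 2)
            if shared_ninemers(a.sequence, b.sequence)
        }
        got = {frozenset(e) for e in graph.edges()}
        assert got == expected
        assert expected  # the fixture actually exercises the index


class TestConnectedComponents:
    def test_no_edges_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        comps = connected_components(g)
        assert sorted(map(tuple, comps)) == [("a",), ("b",), ("c",), ("d",)]

    def test_chain_plus_isolated(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_node("d")
        assert connected_components(g) == [["a", "b", "c"], ["d"]]

    def test_sorted_by_size_then_id(self):
        g = nx.Graph([("x", "y"), ("a", "b")])
        assert connected_components(g) == [["a", "b"], ["x", "y"]]


class TestLaplacian:
    def test_triangle(self):
        g = nx.complete_graph(3)
        L = laplacian(g, [0, 1, 2])
        assert np.array_equal(np.diag(L), [2, 2, 2])
        assert np.all(L - np.diag(np.diag(L)) == -1 + np.eye(3))
        assert np.linalg.eigvalsh(L) == pytest.approx([0, 3, 3], abs=1e-9)

    def test_single_edge(self):
        g = nx.Graph([("u", "v")])
        L = laplacian(g, ["u", "v"])
        assert np.array_equal(L, [[1, -1], [-1, 1]])
        assert np.linalg.eigvalsh(L) == pytest.approx([0, 2], abs=1e-12)

    def test_rows_sum_to_zero_and_psd(self, rng):
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        L = laplacian(g, sorted(g.nodes))
        assert np.allclose(L.sum(axis=1), 0)
        assert np.linalg.eigvalsh(L).min() > -1e-10


class TestFiedlerVector:
    def test_k2_closed_form(self):
        lam2, v2 = fiedler_vector(nx.Graph([("u", "v")]), ["u", "v"])
        assert lam2 == pytest.approx(2.0, abs=1e-9)

    def test_k4_closed_form(self):
        g = nx.complete_graph(4)
        lam2, _ = fiedler_vector(g, list(range(4)))
        assert lam2 == pytest.approx(4.0, abs=1e-9)

    def test_two_triangles_separated_by_sign(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        nodes = list(range(6))
        _, v2 = fiedler_vector(g, nodes)
        left = {n for n, v in zip(nodes, v2) if v < 0}
        assert left in ({0, 1, 2}, {3, 4, 5})

    def test_sign_convention_deterministic(self):
        g, *_ = two_cliques_with_bridge()
        nodes = sorted(g.nodes)
        _, v2a = fiedler_vector(g, nodes)
        _, v2b = fiedler_vector(g, nodes)
        assert np.array_equal(v2a, v2b)
        nz = np.flatnonzero(np.abs(v2a) > 1e-12)
        assert v2a[nz[0]] > 0

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            fiedler_vector(g, ["a"])


class TestSparsity:
    def test_path_prefix(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        assert sparsity(g, {"a", "b"}, ["a", "b", "c", "d"]) == pytest.approx(0.5)

    def test_two_cliques_bridge(self):
        g, left, right = two_cliques_with_bridge()
        assert sparsity(g, left, left + right) == pytest.approx(1 / 5)

    def test_single_node_equals_degree(self):
        g, left, right = two_cliques_with_bridge()
        assert sparsity(g, {left[0]}, left + right) == 5  # 4 clique edges + bridge

    def test_empty_or_full_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError):
            sparsity(g, set(), ["a", "b", "c"])
        with pytest.raises(ValueError):
            sparsity(g, {"a", "b", "c"}, ["a", "b", "c"])


class TestSweepCut:
    def test_two_cliques_bridge_optimal(self):
        g, left, right = two_cliques_with_bridge()
        cut = sweep_cut(g, left + right)
        assert cut.sparsity == pytest.approx(1 / 5)
        assert cut.cut_edges == 1
        assert {frozenset(cut.side_S), frozenset(cut.side_complement)} == {
            frozenset(left),
            frozenset(right),
        }
        assert cut.sparsity == exhaustive_min_sparsity(g, left + right)

    def test_path_of_four_middle_cut(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        cut = sweep_cut(g, ["a", "b", "c", "d"])
        assert cut.sparsity == pytest.approx(0.5)
        assert cut.sparsity == exhaustive_min_sparsity(g, ["a", "b", "c", "d"])
        assert sorted(map(sorted, [cut.side_S, cut.side_complement])) == [
            ["a", "b"],
            ["c", "d"],
        ]

    def test_cycle_matches_exhaustive(self):
        g = nx.cycle_graph(8)
        cut = sweep_cut(g, list(range(8)))
        assert cut.sparsity == pytest.approx(exhaustive_min_sparsity(g, range(8)))

    def test_internal_consistency_on_random_graphs(self):
        # the sweep minimum can exceed the exhaustive optimum (it is an
        # approximation) but never the other way round
        for seed in range(12):
            g = nx.gnp_random_graph(10, 0.35, seed=seed)
            comp = max(nx.connected_components(g), key=len)
            if len(comp) < 3:
                continue
            comp = sorted(comp)
            cut = sweep_cut(g, comp)
            assert cut.sparsity == pytest.approx(
                sparsity(g, cut.side_S, comp)
            )
            assert cut.sparsity >= exhaustive_min_sparsity(g, comp) - 1e-12


class TestPartitionGroups:
    def test_small_components_untouched(self, rng):
        peptides = [
            Peptide(id=f"p{i}", sequence=random_peptide(rng, 12)) for i in range(12)
        ]
        graph = build_similarity_graph(peptides)
        groups, cut_edges, n_splits = partition_groups(graph, max_group_size=3)
        assert cut_edges == 0 and n_splits == 0
        assert sorted(map(tuple, groups)) == sorted(
            map(tuple, connected_components(graph))
        )

    def test_two_cliques_bridge_split(self):
        g, left, right = two_cliques_with_bridge()
        groups, cut_edges, n_splits = partition_groups(g, max_group_size=6)
        assert cut_edges == 1 and n_splits == 1
        assert sorted(len(g_) for g_ in groups) == [5, 5]

    def test_recursive_splitting_terminates(self):
        g = nx.path_graph(range(40))
        groups, cut_edges, n_splits = partition_groups(g, max_group_size=12)
        assert n_splits >= 2
        assert all(len(grp) <= 12 for grp in groups)
        # a path loses exactly one edge per split
        assert cut_edges == n_splits
        assert sum(len(grp) for grp in groups) == 40


class TestAssignFolds:
    def test_singletons_balance_exactly(self):
        groups = [[f"p{i}"] for i in range(10)]
        assignment = assign_folds(groups, k=5)
        assert assignment.fold_sizes == [2] * 5

    def test_greedy_hand_simulation(self):
        groups = [
            ["a1", "a2", "a3", "a4", "a5"],
            ["b1", "b2", "b3", "b4"],
            ["c1", "c2", "c3"],
            ["d1", "d2"],
            ["e1"],
        ]
        assignment = assign_folds(groups, k=2)
        assert sorted(assignment.fold_sizes) == [7, 8]
        fold_of_group = {g[0]: assignment.fold_of[g[0]] for g in groups}
        # 5 -> fold 1; 4 -> fold 2; 3 -> fold 2 (4<5); 2 -> fold 1; 1 -> fold 1
        assert fold_of_group["a1"] == 1
        assert fold_of_group["b1"] == 2
        assert fold_of_group["c1"] == 2
        assert fold_of_group["d1"] == 1
        assert fold_of_group["e1"] == 1

    def test_groups_stay_whole(self):
        groups = [["x1", "x2", "x3"], ["y1", "y2"], ["z1"]]
        assignment = assign_folds(groups, k=2)
        for g in groups:
            assert len({assignment.fold_of[m] for m in g}) == 1

    def test_fewer_groups_than_folds_flagged(self):
        assignment = assign_folds([["a"], ["b"]], k=4)
        assert assignment.has_empty_folds

    def test_k_less_than_two_rejected(self):
        with pytest.raises(ValueError):
            assign_folds([["a"]], k=1)


class TestEndToEnd:
    def test_pure_components_give_zero_overlap(self, rng):
        from rtamhc.synthetic import SyntheticSpec, generate_peptides

        spec = SyntheticSpec(n_peptides=100, family_fraction=0.4, seed=17)
        peptides = generate_peptides(spec, np.random.default_rng(17))
        assignment = build_fold_assignment(peptides, k=5)
        if assignment.n_splits == 0:
            assert assignment.cross_fold_shared_9mer_pairs == 0
            assert assignment.cross_fold_shared_fraction == 0.0
        shared, fraction = overlap_report(assignment, peptides)
        assert shared == assignment.cross_fold_shared_9mer_pairs
        assert sum(assignment.fold_sizes) == len(peptides)
        assert set(assignment.fold_of) == {p.id for p in peptides}

    def test_overlap_equals_cut_edges_on_forced_split(self):
        # one big family forces a split; the removed edges reappear as
        # the cross-fold shared-pair count
        base = "ACDEFGHIKLMNPQRSTVWY"[:15]
        peptides = []
        for i in range(6):
            peptides.append(Peptide(id=f"a{i}", sequence="W" + base[:12] + "YY"))
        for i in range(6):
            peptides.append(Peptide(id=f"b{i}", sequence="C" + base[2:14] + "HH"))
        assignment = build_fold_assignment(peptides, k=2, max_group_size=6)
        graph = build_similarity_graph(peptides)
        shared, _ = overlap_report(assignment, peptides)
        assert shared == assignment.cross_fold_shared_9mer_pairs

    def test_balance_bound(self, rng):
        from rtamhc.synthetic import SyntheticSpec, generate_peptides

        spec = SyntheticSpec(n_peptides=150, family_fraction=0.5, seed=29)
        peptides = generate_peptides(spec, np.random.default_rng(29))
        assignment = build_fold_assignment(peptides, k=5)
        largest = max(
            len(c)
            for c in connected_components(build_similarity_graph(peptides))
        )
        spread = max(assignment.fold_sizes) - min(assignment.fold_sizes)
        assert spread <= max(largest, int(np.ceil(len(peptides) / 5)))
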