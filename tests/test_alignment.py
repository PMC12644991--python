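import networkx as nx
import numpy as np
import pytest

from fwalign.alignment import (Alignment, AlignmentError, GAParams,
                               align_replicated, brute_force_align, ga_align,
                               s3_score, write_alignment)

from conftest import relabel_disjoint

TINY_GA = dict(population_size=60, generations=80, elite_fraction=0.5)


def worked_example():
    """6-node pair: 7 edges in G1, 8 in the induced G2 region, 6 conserved."""
    cycle = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]
    G1 = nx.Graph(cycle + [(0, 2)])
    G2 = nx.Graph(cycle + [(1, 3), (2, 4)])
    return G1, G2, {i: i for i in range(6)}


class TestS3Score:
    def test_worked_example_six_sevens_eight(self):
        G1, G2, f = worked_example()
        assert s3_score(G1, G2, f) == pytest.approx(6 / 9)
        assert round(s3_score(G1, G2, f), 2) == 0.67

    def test_identity_on_equal_graphs_is_one(self):
        G = nx.petersen_graph()
        assert s3_score(G, G, {v: v for v in G.nodes}) == 1.0

    def test_no_conserved_edges_is_zero(self):
        G1 = nx.path_graph(4)
        G2 = nx.Graph([(0, 2), (1, 3)])
        G2.add_nodes_from(range(4))
        assert s3_score(G1, G2, {v: v for v in G1.nodes}) == 0.0

    def test_edgeless_regions_score_one_by_convention(self):
        G1 = nx.empty_graph(3)
        G2 = nx.empty_graph(5)
        assert s3_score(G1, G2, {v: v for v in G1.nodes}) == 1.0

    def test_non_injective_map_rejected(self):
        G1, G2, _ = worked_example()
        with pytest.raises(AlignmentError, match="injective"):
            s3_score(G1, G2, {v: 0 for v in G1.nodes})

    def test_partial_map_rejected(self):
        G1, G2, f = worked_example()
        del f[0]
        with pytest.raises(AlignmentError, match="total"):
            s3_score(G1, G2, f)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_set_arithmetic(self, seed):
        """Recount the three terms of the score by raw set arithmetic."""
        rng = np.random.default_rng(seed)
        n1, n2 = 6, 8
        G1 = nx.gnp_random_graph(n1, 0.5, seed=seed)
        G2 = nx.gnp_random_graph(n2, 0.5, seed=seed + 100)
        perm = rng.permutation(n2)[:n1]
        f = {i: int(perm[i]) for i in range(n1)}
        mapped = {frozenset((f[u], f[v])) for u, v in G1.edges}
        e2_region = {frozenset(e) for e in G2.subgraph(perm.tolist()).edges}
        conserved = len(mapped & e2_region)
        expected = (
            1.0 if len(G1.edges) + len(e2_region) == 0
            else conserved / (len(G1.edges) + len(e2_region) - conserved)
        )
        assert s3_score(G1, G2, f) == pytest.approx(expected)

    def test_invariant_under_relabelling(self):
        G1, G2, f = worked_example()
        H2 = relabel_disjoint(G2)
        g = {v: f"b{f[v]}" for v in f}
        assert s3_score(G1, H2, g) == s3_score(G1, G2, f)


class TestBruteForce:
    def test_identical_path_graphs(self):
        G = nx.path_graph(4)
        assert brute_force_align(G, G).s3 == 1.0

    def test_triangle_into_square(self):
        tri = nx.complete_graph(3)
        square = nx.cycle_graph(4)
        best = brute_force_align(tri, relabel_disjoint(square))
        # any 3 nodes of a 4-cycle induce a path (2 edges); 2 conserved
        assert best.s3 == pytest.approx(2 / 3)

    def test_size_guard(self):
        G = nx.path_graph(9)
        with pytest.raises(AlignmentError, match="limited"):
            brute_force_align(G, G)

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_random_injections(self, seed):
        rng = np.random.default_rng(seed)
        G1 = nx.gnp_random_graph(6, 0.5, seed=seed)
        G2 = relabel_disjoint(nx.gnp_random_graph(8, 0.5, seed=seed + 50))
        nodes2 = sorted(G2.nodes)
        best = brute_force_align(G1, G2).s3
        for _ in range(1000):
            perm = rng.permutation(len(nodes2))[:6]
            f = {i: nodes2[perm[i]] for i in G1.nodes}
            assert s3_score(G1, G2, f) <= best + 1e-12


class TestGA:
    def test_self_alignment_is_identity(self, small_control):
        G = small_control.to_undirected()
        res = ga_align(G, G, GAParams(**TINY_GA, n_runs=1, seed=3))
        assert res.alignment.s3 == 1.0
        assert res.alignment.is_identity_on(G.nodes)

    def test_deterministic_given_seed(self):
        G1 = nx.gnp_random_graph(10, 0.3, seed=4)
        G2 = relabel_disjoint(nx.gnp_random_graph(12, 0.3, seed=5))
        p = GAParams(**TINY_GA, n_runs=1, seed=11)
        r1 = ga_align(G1, G2, p)
        r2 = ga_align(G1, G2, p)
        assert r1.alignment.mapping == r2.alignment.mapping
        assert r1.trace == r2.trace

    def test_trace_is_monotone_nondecreasing(self):
        G1 = nx.gnp_random_graph(12, 0.3, seed=6)
        G2 = relabel_disjoint(nx.gnp_random_graph(14, 0.3, seed=7))
        res = ga_align(G1, G2, GAParams(**TINY_GA, n_runs=1, seed=2))
        assert all(b >= a - 1e-12 for a, b in zip(res.trace, res.trace[1:]))

    def test_g1_larger_than_g2_rejected(self):
        with pytest.raises(AlignmentError, match="smaller"):
            ga_align(nx.path_graph(5), nx.path_graph(3),
                     GAParams(**TINY_GA, n_runs=1))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(4, 8))
        G1 = nx.gnp_random_graph(n1, 0.45, seed=seed)
        G2 = relabel_disjoint(nx.gnp_random_graph(n1 + 1, 0.45, seed=seed + 10))
        bf = brute_force_align(G1, G2)
        ga = ga_align(G1, G2, GAParams(population_size=200, generations=120,
                                       elite_fraction=0.5, n_runs=1, seed=seed))
        assert ga.alignment.s3 == pytest.approx(bf.s3, abs=1e-12)

    def test_swap_symmetry_for_equal_sizes(self):
        """With |V1| = |V2| the optimal score is symmetric in the roles."""
        G1 = nx.gnp_random_graph(6, 0.5, seed=8)
        G2 = relabel_disjoint(nx.gnp_random_graph(6, 0.5, seed=9))
        assert brute_force_align(G1, G2).s3 == pytest.approx(
            brute_force_align(G2, G1).s3)

    def test_node_conservation_objective_still_reports_s3(self):
        G1 = nx.gnp_random_graph(8, 0.4, seed=12)
        G2 = relabel_disjoint(nx.gnp_random_graph(9, 0.4, seed=13))
        res = ga_align(G1, G2, GAParams(**TINY_GA, n_runs=1, seed=1,
                                        objective="node_conservation"))
        assert 0.0 <= res.alignment.s3 <= 1.0
        assert res.alignment.s3 == pytest.approx(
            s3_score(G1, G2, res.alignment.mapping))


class TestReplication:
    def test_single_run_sd_zero(self):
        G = nx.cycle_graph(8)
        rep = align_replicated(G, G, GAParams(**TINY_GA, n_runs=1, seed=0))
        assert rep.sd == 0.0 and rep.mean == 1.0

    def test_identical_graphs_mean_one_any_runs(self, small_control):
        G = small_control.to_undirected()
        rep = align_replicated(G, G, GAParams(**TINY_GA, n_runs=3, seed=1))
        assert rep.mean == 1.0 and rep.sd == 0.0

    def test_planted_solution_not_undershot(self, small_pair):
        """The replicated GA scores at least the planted survivor mapping."""
        G1, G2 = (small_pair.drought.to_undirected(),
                  small_pair.control.to_undirected())
        survivors = [v for v in G1.nodes if v in G2]
        planted = {v: v for v in survivors}
        # extend the survivor identity to a total injection
        free = [v for v in sorted(G2.nodes, key=str) if v not in survivors]
        for v in sorted(G1.nodes, key=str):
            if v not in planted:
                planted[v] = free.pop()
        planted_score = s3_score(G1, G2, planted)
        rep = align_replicated(G1, G2, GAParams(
            population_size=200, generations=150, elite_fraction=0.5,
            n_runs=3, seed=4))
        assert rep.mean >= planted_score - 1e-9

    def test_alignment_file_round_trip_fields(self, tmp_path):
        G = nx.path_graph(5)
        rep = align_replicated(G, G, GAParams(**TINY_GA, n_runs=1, seed=0))
        out = tmp_path / "aln.tsv"
        write_alignment(rep.best, out, GAParams(**TINY_GA, n_runs=1, seed=0))
        lines = out.read_text().splitlines()
        assert lines[0].startswith("# s3=1.0")
        assert lines[2] == "g1_node\tg2_node\tconserved_degree"
        assert len(lines) == 3 + 5
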