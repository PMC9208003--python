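from itertools import permutations

import numpy as np
import pytest

from nbhdclass import (
    PARAMETER_CODES,
    bauer_laplacian,
    build_complex,
    chung_laplacian,
    chung_spectral_gap,
    degree_profile,
    evaluate_parameter,
    fagiolo_cc,
    from_edge_list,
    permute_vertices,
    spectrum_summary,
    transition_matrix,
    transitive_3clique_count,
    transitive_cc,
)

from conftest import complete_reciprocal, random_digraph


def brute_s2(g, v0):
    """Directed 3-cliques containing v0 by exhaustive ordered triples."""
    a = g.dense()
    count = 0
    for tup in permutations(range(g.num_vertices), 3):
        if v0 in tup and a[tup[0], tup[1]] and a[tup[0], tup[2]] \
                and a[tup[1], tup[2]]:
            count += 1
    return count


class TestClusteringCoefficients:
    def test_fagiolo_complete_reciprocal(self, k3):
        assert fagiolo_cc(k3, 0) == pytest.approx(1.0)

    def test_fagiolo_cycle(self, c3):
        assert fagiolo_cc(c3, 0) == pytest.approx(0.5)

    def test_fagiolo_no_triangle(self, path3):
        assert fagiolo_cc(path3, 0) == 0.0

    def test_fagiolo_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(13)
        for _ in range(30):
            g = random_digraph(12, 0.35, rng)
            h = nx.DiGraph(g.arcs())
            h.add_nodes_from(range(g.num_vertices))
            ref = nx.clustering(h)
            for v in range(g.num_vertices):
                assert fagiolo_cc(g, v) == pytest.approx(ref[v], abs=1e-12)

    def test_s2_examples(self, t3, c3, k3):
        assert transitive_3clique_count(t3, 0) == 1
        assert transitive_3clique_count(c3, 0) == 0
        assert all(transitive_3clique_count(k3, v) == 6 for v in range(3))

    def test_s2_against_brute_force_and_flag_complex(self):
        rng = np.random.default_rng(19)
        for _ in range(60):
            n = int(rng.integers(3, 13))
            g = random_digraph(n, 0.4, rng)
            v = int(rng.integers(n))
            two_simplices = build_complex(g, 2).simplices_by_dim
            incidence = (
                sum(1 for s in two_simplices[2] if v in s)
                if len(two_simplices) > 2 else 0
            )
            assert transitive_3clique_count(g, v) == brute_s2(g, v)
            assert transitive_3clique_count(g, v) == incidence

    def test_printed_closed_form_for_s2_disagrees_with_direct_count(self, k3):
        # the published closed form 2*t - sum(a_ij a_jk a_ki) over ordered
        # pairs evaluates to 14 on the complete reciprocal 3-graph, while
        # the direct count of directed 3-cliques at any vertex is 6; the
        # direct count is the implementation
        a = k3.dense()
        i = 0
        t2 = float((a[i] + a[:, i]) @ (a + a.T) @ (a[i] + a[:, i].T))  # 2*t
        cyc = float(a[i] @ a @ a[:, i])
        assert t2 - cyc == 14
        assert transitive_3clique_count(k3, i) == 6

    def test_tcc_examples(self, t3, c3, k3):
        assert transitive_cc(k3, 0) == pytest.approx(1.0)
        assert transitive_cc(t3, 0) == pytest.approx(0.5)
        assert transitive_cc(c3, 0) == 0.0

    @pytest.mark.parametrize("n", range(3, 9))
    def test_tcc_is_one_on_complete_reciprocal_digraphs(self, n):
        # the denominator equals the attainable maximum: on a complete
        # reciprocal digraph every ordered triple through v0 is realised
        g = complete_reciprocal(n)
        assert transitive_cc(g, 0) == pytest.approx(1.0)
        prof = degree_profile(g, 0)
        denom = prof.deg * (prof.deg - 1) - prof.ind * prof.oud - prof.reciprocal
        assert brute_s2(g, 0) == denom

    def test_coefficients_bounded_in_unit_interval(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n = int(rng.integers(2, 26))
            g = random_digraph(n, float(rng.choice([0.1, 0.3, 0.6])), rng)
            v = int(rng.integers(n))
            assert 0.0 <= fagiolo_cc(g, v) <= 1.0 + 1e-12
            assert 0.0 <= transitive_cc(g, v) <= 1.0 + 1e-12


class TestTransitionMatrix:
    def test_cycle_is_permutation_matrix(self, c3):
        p = transition_matrix(c3)
        assert np.array_equal(p, np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]]))

    def test_complete_reciprocal(self, k3):
        p = transition_matrix(k3)
        expected = (np.ones((3, 3)) - np.eye(3)) / 2
        assert np.allclose(p, expected)

    def test_sink_row_is_zero(self, path3):
        p = transition_matrix(path3)
        assert np.all(p[2] == 0)

    def test_rows_sum_to_one_for_positive_out_degree(self):
        rng = np.random.default_rng(37)
        g = random_digraph(20, 0.2, rng)
        p = transition_matrix(g)
        oud = g.out_degrees()
        assert np.allclose(p[oud > 0].sum(axis=1), 1.0)

    def test_spectral_radius_one_when_strongly_connected(self, c3, k3):
        for g in (c3, k3):
            assert spectrum_summary(transition_matrix(g)).radius == \
                pytest.approx(1.0)

    def test_reversed_uses_in_degrees(self, path3):
        p = transition_matrix(path3, reversed=True)
        assert np.all(p[0] == 0)  # vertex 0 has in-degree 0
        assert p[1, 2] == 1.0


class TestLaplacians:
    def test_bauer_cycle_spectrum(self, c3):
        s = spectrum_summary(bauer_laplacian(c3))
        assert s.moduli == pytest.approx((np.sqrt(3), np.sqrt(3), 0.0))

    def test_bauer_source_vertex_gives_zero_row(self, t3):
        lap = bauer_laplacian(t3)
        assert np.all(lap[0] == 0)
        eigs = np.sort(np.abs(np.linalg.eigvals(lap)))
        assert eigs == pytest.approx([0.0, 1.0, 1.0])

    def test_bauer_complete_reciprocal(self, k3):
        eigs = np.sort(np.abs(np.linalg.eigvals(bauer_laplacian(k3))))
        assert eigs == pytest.approx([0.0, 1.5, 1.5])

    def test_chung_cycle(self, c3):
        eigs = np.linalg.eigvalsh(chung_laplacian(c3))
        assert eigs == pytest.approx([0.0, 1.5, 1.5], abs=1e-9)

    def test_chung_two_cycle(self):
        g = from_edge_list([(0, 1), (1, 0)])
        eigs = np.linalg.eigvalsh(chung_laplacian(g))
        assert eigs == pytest.approx([0.0, 2.0], abs=1e-9)

    def test_chung_requires_strong_connectivity(self, t3):
        with pytest.raises(ValueError, match="strongly connected"):
            chung_laplacian(t3)

    def test_chung_gap_restricts_to_largest_scc(self, t3, c3, k3):
        assert chung_spectral_gap(t3) == 0.0  # singleton SCCs
        assert chung_spectral_gap(c3) == pytest.approx(1.5)
        assert chung_spectral_gap(k3) == pytest.approx(1.5)

    def test_chung_gap_obeys_transition_spectrum_bounds(self):
        # min_{i != 0} (1 - |rho_i|) <= 2*lambda and
        # lambda <= min_{i != 0} (1 - Re rho_i): the Cheeger-style
        # comparison between the Laplacian gap and the transition
        # spectrum (the bare lower bound without the factor 2 fails on
        # random strongly connected digraphs)
        rng = np.random.default_rng(43)
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 21))
            g = random_digraph(n, 0.35, rng)
            from nbhdclass import largest_scc
            if len(largest_scc(g)) != n:
                continue
            lam = chung_spectral_gap(g)
            rho = np.linalg.eigvals(transition_matrix(g))
            rho = np.delete(rho, np.argmin(np.abs(rho - 1.0)))
            lower = np.min(1.0 - np.abs(rho))
            upper = np.min(1.0 - np.real(rho))
            assert lower - 1e-8 <= 2 * lam
            assert lam <= upper + 1e-8
            checked += 1


class TestSpectrumSummary:
    def test_complete_reciprocal_adjacency(self, k3):
        s = spectrum_summary(k3.dense().astype(float))
        assert s.radius == pytest.approx(2.0)
        assert s.gap_high == pytest.approx(1.0)

    def test_cycle_adjacency_has_no_gap(self, c3):
        s = spectrum_summary(c3.dense().astype(float))
        assert s.radius == pytest.approx(1.0)
        assert s.gap_high == pytest.approx(0.0)

    def test_nilpotent_adjacency(self, t3):
        s = spectrum_summary(t3.dense().astype(float))
        assert s.radius == pytest.approx(0.0)
        assert s.gap_high == 0.0
        assert s.gap_low == 0.0

    def test_empty_matrix_convention(self):
        s = spectrum_summary(np.zeros((0, 0)))
        assert (s.radius, s.gap_high, s.gap_low) == (0.0, 0.0, 0.0)


class TestEvaluateParameter:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("ec", 1.0),
            ("size", 3.0),
            ("tcc", 0.5),
            ("deg", 2.0),
        ],
    )
    def test_dispatch_on_transitive_triangle(self, t3, code, expected):
        assert evaluate_parameter(code, t3, centre=0) == pytest.approx(expected)

    def test_clsg_on_cycle(self, c3):
        assert evaluate_parameter("clsg", c3) == pytest.approx(1.5)

    def test_blsr_on_cycle(self, c3):
        assert evaluate_parameter("blsr", c3) == pytest.approx(np.sqrt(3))

    def test_unknown_code_lists_valid(self, c3):
        with pytest.raises(KeyError, match="fcc"):
            evaluate_parameter("nope", c3)

    def test_centre_required_for_centre_codes(self, c3):
        with pytest.raises(ValueError, match="centre"):
            evaluate_parameter("tcc", c3)

    def test_degenerate_graphs_evaluate_to_zero(self):
        g = from_edge_list([], num_vertices=1)
        for code in ("asg", "asr", "blsg", "clsg", "tpsr", "nbc"):
            val = evaluate_parameter(code, g)
            assert val == (1.0 if code == "nbc" else 0.0)

    def test_all_codes_invariant_under_relabelling(self):
        rng = np.random.default_rng(47)
        graph_codes = [
            c for c in PARAMETER_CODES
            if c not in ("fcc", "tcc", "deg", "ind", "oud")
        ]
        for _ in range(8):
            g = random_digraph(9, 0.4, rng)
            sigma = rng.permutation(9)
            h = permute_vertices(g, sigma)
            for code in graph_codes:
                assert evaluate_parameter(code, g) == pytest.approx(
                    evaluate_parameter(code, h), abs=1e-8
                ), code
            v = int(rng.integers(9))
            for code in ("fcc", "tcc", "deg", "ind", "oud"):
                assert evaluate_parameter(code, g, centre=v) == pytest.approx(
                    evaluate_parameter(code, h, centre=int(sigma[v])), abs=1e-10
                ), code
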