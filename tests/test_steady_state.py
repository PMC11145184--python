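from fractions import Fraction

import numpy as np
import pytest

import hillbarrier as hb
from hillbarrier.cli_io import make_random_digraph, make_random_pattern_graph
from hillbarrier.steady_state import (
    CycleConditionError,
    _rho_enumeration,
    _rho_minors_exact,
)

from conftest import X_GRID, rationalize


class TestSpanningTrees:
    def test_k2_single_tree(self, k2):
        trees = hb.enumerate_rooted_spanning_trees(k2, "1")
        assert len(trees) == 1
        assert next(iter(trees)).edges == frozenset({("2", "1")})

    def test_reversible_triangle_has_three(self, triangle):
        assert len(hb.enumerate_rooted_spanning_trees(triangle, "a")) == 3

    def test_c2_has_four_rooted_trees(self):
        # the square's 4 undirected spanning trees, each orientable to the root
        G = hb.build_hypercube(2)
        trees = hb.enumerate_rooted_spanning_trees(G, "0")
        assert len(trees) == 4
        for t in trees:
            sources = [i for (i, _) in t.edges]
            assert "0" not in sources and len(t.edges) == 3

    def test_enumeration_cap(self):
        G = hb.build_hypercube(4)
        with pytest.raises(ValueError):
            hb.enumerate_rooted_spanning_trees(G, "0")


class TestTreeCounts:
    def test_c4_printed_count(self):
        G = hb.build_hypercube(4)
        assert hb.count_rooted_spanning_trees(G, "0") == 42_467_328

    def test_c3_matches_enumeration(self):
        G = hb.build_hypercube(3)
        det = hb.count_rooted_spanning_trees(G, "0")
        assert det == len(hb.enumerate_rooted_spanning_trees(G, "0"))

    def test_k2(self, k2):
        assert hb.count_rooted_spanning_trees(k2, "2") == 1


class TestRho:
    def test_k2_proportional_to_1_2(self, k2):
        pv = hb.rho(k2, mode="enumeration")
        # single tree each: rho_1 = rate(2->1) = 1, rho_2 = rate(1->2) = 2
        assert pv.evaluate("1", 1) == 1 and pv.evaluate("2", 1) == 2

    def test_c1_symbolic_monomials(self):
        G = hb.build_hypercube(1, rates={("0", "1"): 3.0, ("1", "0"): 7.0})
        pv = hb.rho(G, mode="enumeration")
        assert pv.coeffs["0"] == (7,)          # k_off
        assert pv.coeffs["1"] == (0, 3)        # k_on * x
        assert pv.degree("1") == 1

    def test_noneq_c2_denominator_degree_3(self):
        rng = np.random.default_rng(8)
        G = rationalize(hb.build_hypercube(2), rng)
        pv = hb.rho(G, mode="enumeration")
        assert pv.denominator_degree() == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_minors_equal_enumeration_exactly(self, seed):
        rng = np.random.default_rng(seed)
        G = rationalize(
            make_random_pattern_graph(2, rng, equilibrium=False, max_copies=1), rng
        )
        assert _rho_enumeration(G, 10).coeffs == _rho_minors_exact(G).coeffs

    def test_matrix_tree_kernel(self):
        """L(G) rho(G) = 0 exactly, coefficient by coefficient."""
        rng = np.random.default_rng(3)
        G = rationalize(make_random_digraph(5, rng), rng)
        pv = hb.rho(G, mode="minors")
        vals = {v: pv.evaluate(v, Fraction(1)) for v in G.vertices}
        for v in G.vertices:
            flux = sum(
                vals[i] * Fraction(G.edges[(i, j)][0])
                for (i, j) in G.edges if j == v
            ) - vals[v] * sum(
                Fraction(G.edges[(i, j)][0]) for (i, j) in G.edges if i == v
            )
            assert flux == 0


class TestSteadyState:
    def test_k2_distribution(self, k2):
        assert np.allclose(hb.steady_state(k2, 1.0), [1 / 3, 2 / 3])

    def test_triangle_uniform(self, triangle):
        assert np.allclose(hb.steady_state(triangle, 1.0), 1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_and_normalization(self, seed):
        G = make_random_pattern_graph(
            2, np.random.default_rng(seed), equilibrium=False
        )
        for x in (0.1, 1.0, 10.0):
            u = hb.steady_state(G, x)
            assert abs(u.sum() - 1.0) < 1e-12
            assert np.all((u > 0) & (u < 1))
            assert np.abs(hb.laplacian(G, x) @ u).max() < 1e-10


class TestCycleCondition:
    def test_uniform_c2_satisfies(self):
        assert hb.cycle_condition_satisfied(hb.build_hypercube(2))

    def test_single_doubled_rate_violates(self):
        G = hb.build_hypercube(2, rates={("0", "1"): 2.0})
        assert not hb.cycle_condition_satisfied(G)

    def test_tree_vacuously_satisfies(self):
        G = hb.build_graph(
            [("a", "b", 5.0, 0), ("b", "a", 1.0, 0),
             ("b", "c", 2.0, 0), ("c", "b", 7.0, 0)],
            {"a": [], "b": [], "c": []},
        )
        assert hb.cycle_condition_satisfied(G)

    def test_non_reversible_rejected(self):
        G = hb.build_graph(
            [("1", "2", 1.0, 0), ("2", "3", 1.0, 0), ("3", "1", 1.0, 0)],
            {"1": [], "2": [], "3": []},
        )
        with pytest.raises(CycleConditionError):
            hb.cycle_condition_satisfied(G)


class TestMuVector:
    def test_c1_monomials(self):
        G = hb.build_hypercube(1, rates={("0", "1"): 3.0, ("1", "0"): 6.0})
        mu = hb.mu_vector(G)
        assert mu.coeffs["0"] == (1.0,)
        assert mu.coeffs["1"] == (0.0, 0.5)    # (k_on/k_off) x

    def test_degree_equals_pattern_size(self):
        G = hb.build_hypercube(2)
        mu = hb.mu_vector(G)
        for v in G.vertices:
            assert mu.degree(v) == len(G.binding_pattern[v])

    def test_equilibrium_routes_agree(self):
        """mu-normalization (partition function) vs Matrix-Tree minors."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            G = make_random_pattern_graph(2, rng, a=1.0, equilibrium=True)
            for x in X_GRID:
                d = np.abs(
                    hb.steady_state(G, x) - hb.equilibrium_steady_state(G, x)
                ).max()
                assert d < 1e-10

    def test_nonequilibrium_rejected(self):
        G = hb.build_hypercube(2, rates={("0", "1"): 2.0})
        with pytest.raises(CycleConditionError):
            hb.mu_vector(G)

    def test_reference_must_be_unbound(self):
        G = hb.build_hypercube(1)
        with pytest.raises(CycleConditionError):
            hb.mu_vector(G, reference="1")


class TestPathEntropy:
    def test_k2_log_ratio(self, k2):
        assert hb.path_entropy(k2, ["1", "2"]) == pytest.approx(np.log(2.0))

    def test_antisymmetry_and_additivity(self, triangle):
        fwd = hb.path_entropy(triangle, ["a", "b", "c"])
        bwd = hb.path_entropy(triangle, ["c", "b", "a"])
        assert fwd + bwd == pytest.approx(0.0, abs=1e-12)
        ab = hb.path_entropy(triangle, ["a", "b"])
        bc = hb.path_entropy(triangle, ["b", "c"])
        assert fwd == pytest.approx(ab + bc, abs=1e-12)

    def test_equilibrium_cycle_zero(self):
        rng = np.random.default_rng(5)
        G = make_random_pattern_graph(2, rng, a=1.0, equilibrium=True, max_copies=1)
        cyc = ["0", "1", "1+2", "2", "0"]
        cyc = [f"{v}.0" for v in cyc]
        assert abs(hb.path_entropy(G, cyc, x=3.7)) < 1e-12

    def test_missing_reverse_edge_rejected(self):
        G = hb.build_graph(
            [("1", "2", 1.0, 0), ("2", "3", 1.0, 0), ("3", "1", 1.0, 0)],
            {"1": [], "2": [], "3": []},
        )
        with pytest.raises(ValueError):
            hb.path_entropy(G, ["1", "2"])
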