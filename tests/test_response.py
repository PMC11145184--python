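import numpy as np
import pytest

import hillbarrier as hb
from hillbarrier.cli_io import make_random_pattern_graph
from hillbarrier.steady_state import CycleConditionError

from conftest import X_GRID


class TestResponseValue:
    def test_unit_weights(self, c1):
        w = {v: 1.0 for v in c1.vertices}
        for x in (0.1, 1.0, 10.0):
            assert hb.response_value(c1, w, x) == pytest.approx(1.0)

    def test_zero_weights(self, c1):
        w = {v: 0.0 for v in c1.vertices}
        assert hb.response_value(c1, w, 1.0) == 0.0

    def test_michaelis_menten_half_point(self):
        G = hb.build_hypercube(1, rates={("0", "1"): 2.0, ("1", "0"): 6.0})
        w = hb.fractional_saturation_weights(G)
        assert hb.response_value(G, w, 3.0) == pytest.approx(0.5)  # x = k_off/k_on

    def test_invalid_weight_rejected(self, c1):
        with pytest.raises(ValueError):
            hb.response_value(c1, {v: 2.0 for v in c1.vertices}, 1.0)


class TestFractionalSaturation:
    def test_c2_weights(self):
        G = hb.build_hypercube(2)
        w = hb.fractional_saturation_weights(G)
        assert w == {"0": 0.0, "1": 0.5, "2": 0.5, "1+2": 1.0}

    def test_c4_three_bound(self):
        G = hb.build_hypercube(4)
        w = hb.fractional_saturation_weights(G)
        assert w["1+2+3"] == pytest.approx(0.75)
        assert all(0.0 <= lam <= 1.0 for lam in w.values())


class TestEquilibriumRationalForm:
    def test_c1_closed_form(self):
        G = hb.build_hypercube(1, rates={("0", "1"): 2.0, ("1", "0"): 6.0})
        r = hb.equilibrium_rational_form(G, hb.fractional_saturation_weights(G))
        # r = x / (K + x) with K = k_off/k_on = 3, up to overall scale
        assert r.alpha[0] == 0.0
        assert r.beta[0] / r.beta[1] == pytest.approx(3.0)
        assert r.alpha[1] == pytest.approx(r.beta[1])

    def test_unit_weights_give_alpha_equal_beta(self):
        G = make_random_pattern_graph(2, np.random.default_rng(0), equilibrium=True)
        r = hb.equilibrium_rational_form(G, {v: 1.0 for v in G.vertices})
        assert np.allclose(r.alpha, r.beta)

    @pytest.mark.parametrize("seed", range(8))
    def test_constraints_and_pointwise_agreement(self, seed):
        """Equilibrium responses obey beta_i > 0, 0 <= alpha_i <= beta_i,
        degree l = max bound sites, and match the direct route."""
        rng = np.random.default_rng(seed)
        G = make_random_pattern_graph(2, rng, a=1.0, equilibrium=True)
        lam = {v: float(rng.uniform(0, 1)) for v in G.vertices}
        r = hb.equilibrium_rational_form(G, lam)
        assert r.constraint_flag
        assert r.l == max(len(G.binding_pattern[v]) for v in G.vertices)
        for x in X_GRID:
            assert abs(float(r(x)) - hb.response_value(G, lam, x)) < 1e-10

    def test_mutual_exclusion_degree_below_m(self):
        G = hb.build_hypercube_substructure(2, removed_vertices=[{1, 2}])
        r = hb.equilibrium_rational_form(G, hb.fractional_saturation_weights(G))
        assert r.l == 1 and G.n_sites == 2
        assert r.constraint_flag

    def test_convex_combination_of_weights_stays_valid(self):
        rng = np.random.default_rng(11)
        G = make_random_pattern_graph(2, rng, a=1.0, equilibrium=True)
        w1 = {v: float(rng.uniform(0, 1)) for v in G.vertices}
        w2 = {v: float(rng.uniform(0, 1)) for v in G.vertices}
        for t in (0.25, 0.5, 0.75):
            w = {v: t * w1[v] + (1 - t) * w2[v] for v in G.vertices}
            assert hb.equilibrium_rational_form(G, w).constraint_flag

    def test_nonequilibrium_rejected(self):
        G = hb.build_hypercube(2, rates={("0", "1"): 2.0})
        with pytest.raises(CycleConditionError):
            hb.equilibrium_rational_form(G, hb.fractional_saturation_weights(G))


class TestSamplers:
    def test_equilibrium_draw_ranges(self):
        rng = np.random.default_rng(0)
        la, lb = hb.sample_equilibrium_coefficients(2000, 2, 2.0, rng)
        assert lb.min() >= -2.0 and lb.max() <= 2.0
        assert np.all(la <= lb) and la.min() >= -2.0

    def test_seed_reproducibility(self):
        r1 = hb.sample_equilibrium_response(3, 2.0, np.random.default_rng(5))
        r2 = hb.sample_equilibrium_response(3, 2.0, np.random.default_rng(5))
        assert r1.alpha == r2.alpha and r1.beta == r2.beta

    def test_constrained_draws_bounded_on_grid(self):
        """Responses under the coefficient constraints stay in [0, 1]."""
        rng = np.random.default_rng(1)
        xs = np.logspace(-4, 4, 33)
        la, lb = hb.sample_equilibrium_coefficients(10_000, 2, 2.0, rng)
        alpha, beta = 10.0**la, 10.0**lb
        num = alpha @ np.vander(xs, 3, increasing=True).T
        den = beta @ np.vander(xs, 3, increasing=True).T
        r = num / den
        assert r.min() >= 0.0 and r.max() <= 1.0

    def test_unconstrained_draws_can_violate(self):
        rng = np.random.default_rng(2)
        hits = sum(
            not hb.sample_unconstrained_response(2, 2.0, rng).constraint_flag
            for _ in range(500)
        )
        assert hits > 100  # a substantial fraction violates alpha <= beta

    def test_invalid_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            hb.sample_equilibrium_response(0, 2.0, rng)
        with pytest.raises(ValueError):
            hb.sample_unconstrained_response(2, -1.0, rng)
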