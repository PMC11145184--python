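"""Input-output responses and their equilibrium rational structure.

A response is a nonnegative linear combination of steady-state vertex
probabilities with weights in [0, 1],

    r(x) = sum_i lambda_i u*_i(G),          0 <= lambda_i <= 1,

viewed as a function of the input concentration x.  At thermodynamic
equilibrium r(x) collapses to the universal rational form

    r(x) = (a_0 + a_1 x + ... + a_l x^l) / (b_0 + b_1 x + ... + b_l x^l)

with all b_i > 0 and 0 <= a_i <= b_i, where l is the maximum number of
input sites ever simultaneously bound — irrespective of any other
molecular complexity of G.  Every coefficient vector satisfying these
constraints is realizable by some equilibrium model, so the samplers
here draw coefficients directly when exploring the equilibrium region;
unconstrained draws (a_i > b_i allowed) model what lies beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import LabeledGraph
from .steady_state import CycleConditionError, mu_vector, steady_state


@dataclass(frozen=True)
class RationalResponse:
    """Rational response r(x) = sum(alpha_i x^i) / sum(beta_i x^i).

    Coefficients are stored constant-term first.  ``constraint_flag``
    records whether the equilibrium coefficient constraints
    (beta_i > 0 and 0 <= alpha_i <= beta_i) hold, which guarantees
    0 <= r(x) <= 1 on [0, infinity).
    """

    alpha: tuple
    beta: tuple

    def __post_init__(self):
        if len(self.alpha) != len(self.beta) or len(self.alpha) < 2:
            raise ValueError("alpha and beta must share a length >= 2 (l >= 1)")
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    @property
    def l(self) -> int:
        return len(self.alpha) - 1

    @property
    def constraint_flag(self) -> bool:
        return all(b > 0 for b in self.beta) and all(
            0 <= a <= b for a, b in zip(self.alpha, self.beta)
        )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        num = np.polynomial.polynomial.polyval(x, self.alpha)
        den = np.polynomial.polynomial.polyval(x, self.beta)
        return num / den

    def derivative_polys(self):
        """Numerator N = A'B - AB' and denominator B of r'(x) = N/B^2,
        as constant-first coefficient arrays."""
        A = np.asarray(self.alpha)
        B = np.asarray(self.beta)
        dA = np.polynomial.polynomial.polyder(A)
        dB = np.polynomial.polynomial.polyder(B)
        N = np.polynomial.polynomial.polysub(
            np.polynomial.polynomial.polymul(dA, B),
            np.polynomial.polynomial.polymul(A, dB),
        )
        return N, B

    def scale_input(self, c: float) -> "RationalResponse":
        """The response x -> r(c x): coefficients pick up powers of c.
        Position and steepness are invariant under this rescaling."""
        if c <= 0:
            raise ValueError("scale factor must be > 0")
        pw = c ** np.arange(len(self.alpha))
        return RationalResponse(
            tuple(np.asarray(self.alpha) * pw), tuple(np.asarray(self.beta) * pw)
        )

    def to_json_dict(self):
        return {"alpha": list(self.alpha), "beta": list(self.beta), "l": self.l}


def check_weights(G: LabeledGraph, weights: dict) -> None:
    for v in G.vertices:
        lam = weights.get(v)
        if lam is None or not 0.0 <= lam <= 1.0:
            raise ValueError(f"weight for vertex {v!r} missing or outside [0, 1]")


def response_value(G: LabeledGraph, weights: dict, x) -> float:
    """Direct response sum_i lambda_i u*_i(G) at concentration x."""
    check_weights(G, weights)
    u = steady_state(G, x)
    return float(sum(weights[v] * u[G.index(v)] for v in G.vertices))


def fractional_saturation_weights(G: LabeledGraph) -> dict:
    """Fractional saturation: the mean number of input-bound sites
    divided by the total number of sites, i.e. lambda_i = |pattern_i|/m."""
    if G.n_sites < 1:
        raise ValueError("fractional saturation needs m >= 1")
    return {v: len(G.binding_pattern[v]) / G.n_sites for v in G.vertices}


def equilibrium_rational_form(G: LabeledGraph, weights: dict) -> RationalResponse:
    """Extract the rational coefficients of an equilibrium response.

    With mu_i(G) = gamma_i x^{b_i}, the denominator coefficient of x^j
    is the sum of gamma over vertices with j sites bound, and the
    numerator coefficient additionally weights each gamma by lambda_i.
    The degree l is the maximum number of concurrently bound sites.
    Raises CycleConditionError away from equilibrium, where no such
    universal form exists.
    """
    check_weights(G, weights)
    mu = mu_vector(G)
    l = max(len(G.binding_pattern[v]) for v in G.vertices)
    alpha = [0.0] * (l + 1)
    beta = [0.0] * (l + 1)
    for v in G.vertices:
        b = len(G.binding_pattern[v])
        gamma = float(mu.coeffs[v][b])
        beta[b] += gamma
        alpha[b] += weights[v] * gamma
    if any(bj <= 0 for bj in beta):
        raise CycleConditionError(
            "a binding degree below l is unoccupied; graph vertices are not "
            "reachable by successive input binding"
        )
    return RationalResponse(tuple(alpha), tuple(beta))


# ---------------------------------------------------------------------------
# Coefficient samplers for the universal region
# ---------------------------------------------------------------------------

def sample_equilibrium_coefficients(
    n: int, l: int, a: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of n equilibrium coefficient vectors of degree l:
    log10(beta_i) ~ Uniform(-a, a), then log10(alpha_i) ~
    Uniform(-a, log10(beta_i)), enforcing 0 < alpha_i <= beta_i.
    Returns (log10_alpha, log10_beta), each of shape (n, l+1)."""
    if l < 1 or a <= 0:
        raise ValueError("need l >= 1 and a > 0")
    lb = rng.uniform(-a, a, size=(n, l + 1))
    la = rng.uniform(-a, lb)
    return la, lb


def sample_equilibrium_response(l: int, a: float, rng: np.random.Generator) -> RationalResponse:
    """One draw from the equilibrium coefficient sampler."""
    la, lb = sample_equilibrium_coefficients(1, l, a, rng)
    return RationalResponse(tuple(10.0 ** la[0]), tuple(10.0 ** lb[0]))


def sample_unconstrained_response(l: int, a: float, rng: np.random.Generator) -> RationalResponse:
    """Draw with alpha sampled log-uniform on [-a, a] independently of
    beta, so the equilibrium constraint alpha_i <= beta_i can fail and
    the response may leave [0, 1]."""
    if l < 1 or a <= 0:
        raise ValueError("need l >= 1 and a > 0")
    lb = rng.uniform(-a, a, size=l + 1)
    la = rng.uniform(-a, a, size=l + 1)
    return RationalResponse(tuple(10.0 ** la), tuple(10.0 ** lb))
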