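"""Coarse-graining of a labeled graph onto its input-binding patterns.

Any strongly connected, reversible graph G can be reduced, at steady
state, to a graph C(G) on the binding patterns that actually occur in
G — a substructure of the hypercube C_m.  The coarse edge label into a
pattern block is proportional to that block's Matrix-Tree weight,

    ell(w -> z) = Q * sum_{j in block z} rho_j(G),

with Q a dimensional constant whose value is irrelevant (only label
ratios enter the steady state).  With these labels C(G) satisfies the
cycle condition by construction — even when G does not — and its steady
state is the block sum of G's:

    u*_w(C(G)) = sum_{i in block w} u*_i(G).

The conditional probabilities chi_i = u*_i / (block sum) summarize all
non-input features of G; at thermodynamic equilibrium they are
independent of the input concentration x, which is what collapses every
equilibrium response onto a hypercube substructure.  Nothing is implied
about the *dynamics* of C(G); the construction is a steady-state one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import GraphValidationError, LabeledGraph, build_graph, pattern_name, validate
from .steady_state import cycle_condition_satisfied, equilibrium_steady_state, steady_state


@dataclass(frozen=True)
class CoarseGraph:
    """Coarse-grained graph together with its provenance."""

    graph: LabeledGraph          # vertices are occupied patterns
    partition: dict              # pattern -> tuple of original vertices
    source_vertices: tuple       # vertex order of the original graph
    x: float                     # concentration at which labels were built
    Q: float                     # dimensional constant (irrelevant to u*)


def partition_by_binding_pattern(G: LabeledGraph) -> dict:
    """Partition of G's vertices into blocks of equal binding pattern,
    keyed by the pattern (frozenset of sites)."""
    blocks: dict = {}
    for v in G.vertices:
        blocks.setdefault(G.binding_pattern[v], []).append(v)
    return {s: tuple(vs) for s, vs in blocks.items()}


def coarse_grain(G: LabeledGraph, x, Q: float = 1.0) -> CoarseGraph:
    """Build C(G) at input concentration x.

    Requires G strongly connected and reversible (equilibrium is *not*
    required).  The coarse vertices are the occupied patterns; a coarse
    edge exists wherever some G-edge crosses between two blocks, and is
    flagged as input-binding when the target pattern gains one site.
    """
    rep = validate(G)
    if not (rep["strongly_connected"] and rep["reversible"]):
        raise GraphValidationError(
            "coarse-graining needs a strongly connected, reversible graph"
        )
    if x <= 0:
        raise ValueError("x must be > 0")
    blocks = partition_by_binding_pattern(G)
    u = steady_state(G, x)
    uix = {v: u[G.index(v)] for v in G.vertices}
    block_weight = {s: sum(uix[v] for v in vs) for s, vs in blocks.items()}

    crossing = set()
    for (i, j) in G.edges:
        si, sj = G.binding_pattern[i], G.binding_pattern[j]
        if si != sj:
            crossing.add((si, sj))
    records, patterns = [], {}
    for (si, sj) in sorted(crossing, key=lambda p: (sorted(p[0]), sorted(p[1]))):
        u_name, v_name = pattern_name(si), pattern_name(sj)
        patterns[u_name], patterns[v_name] = si, sj
        flag = 1 if sj > si else 0
        label = Q * block_weight[sj]
        rate = label / x if flag else label   # peel the x factor off binding edges
        records.append((u_name, v_name, rate, flag))
    cg = build_graph(records, patterns, n_sites=G.n_sites)
    if not cycle_condition_satisfied(cg):
        raise GraphValidationError("coarse labels violate the cycle condition")
    return CoarseGraph(cg, blocks, G.vertices, float(x), float(Q))


def coarse_graining_residual(G: LabeledGraph, x, Q: float = 1.0) -> float:
    """Max |u*_w(C(G)) - block sum of u*(G)| over blocks, at input x."""
    cg = coarse_grain(G, x, Q=Q)
    u = steady_state(G, x)
    uc = steady_state(cg.graph, x)
    res = 0.0
    for s, vs in cg.partition.items():
        w = pattern_name(s)
        block = sum(u[G.index(v)] for v in vs)
        res = max(res, abs(uc[cg.graph.index(w)] - block))
    return res


def conditional_probabilities(G: LabeledGraph, x, assume_equilibrium: bool | None = None) -> dict:
    """chi_i: steady-state probability of vertex i conditioned on its
    binding-pattern block; sums to 1 within each block.  Independent of
    x iff G satisfies the cycle condition.

    At equilibrium the steady state is evaluated through the
    partition-function (mu) route, which is exact up to rounding of the
    Boltzmann weights; the Matrix-Tree determinant route is used
    otherwise.  ``assume_equilibrium`` overrides the automatic cycle-
    condition check.
    """
    if assume_equilibrium is None:
        try:
            assume_equilibrium = cycle_condition_satisfied(G)
        except Exception:
            assume_equilibrium = False
    blocks = partition_by_binding_pattern(G)
    u = equilibrium_steady_state(G, x) if assume_equilibrium else steady_state(G, x)
    uix = {v: u[G.index(v)] for v in G.vertices}
    chi = {}
    for s, vs in blocks.items():
        tot = sum(uix[v] for v in vs)
        for v in vs:
            chi[v] = uix[v] / tot
    return chi


def coarse_response(G: LabeledGraph, lambda_weights: dict, x_grid) -> np.ndarray:
    """Input-output response evaluated through the coarse-grained route:

        r(x) = sum_S sum_{i in block S} lambda_i chi_i u*_S(C(G)),

    recomputing C(G), chi and the coarse steady state at each grid
    point.  Agrees with the direct response on G."""
    for v, lam in lambda_weights.items():
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"weight for {v!r} outside [0, 1]")
    out = np.empty(len(x_grid))
    for k, x in enumerate(x_grid):
        cg = coarse_grain(G, x)
        chi = conditional_probabilities(G, x)
        uc = steady_state(cg.graph, x)
        r = 0.0
        for s, vs in cg.partition.items():
            us = uc[cg.graph.index(pattern_name(s))]
            r += us * sum(lambda_weights[v] * chi[v] for v in vs)
        out[k] = r
    return out
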