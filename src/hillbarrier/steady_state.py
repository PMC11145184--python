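"""Exact steady states of linear-framework graphs.

Two routes to the steady state of a strongly connected graph:

* the general Matrix-Tree route: the kernel vector ``rho(G)`` whose
  component at vertex ``i`` is the sum, over spanning trees rooted at
  ``i``, of the product of effective edge labels — computed either by
  brute-force tree enumeration (the oracle, small graphs only) or as
  first minors of the Laplacian;
* the equilibrium route: when the cycle condition holds (detailed
  balance), the vector ``mu(G)`` of path label-ratio products from a
  reference vertex, which for an input-binding graph is a monomial
  ``gamma_i * x**b_i`` with ``b_i`` the number of bound input sites.

Both normalize to the same steady-state distribution at equilibrium;
away from equilibrium only the Matrix-Tree route applies.  ``log mu(P)``
along a path is the entropy generated along it; the cycle condition
(zero entropy generation over cycles) is the thermodynamic-equilibrium
diagnostic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .graph_core import LabeledGraph, laplacian, validate


class NotStronglyConnectedError(ValueError):
    pass


class CycleConditionError(ValueError):
    """The graph is not at thermodynamic equilibrium (or not reversible)."""


ENUMERATION_CAP = 10  # max vertex count for brute-force tree enumeration


# ---------------------------------------------------------------------------
# Polynomial vectors in the input concentration x
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolyVector:
    """Per-vertex polynomial in x, coefficients indexed by degree.

    ``coeffs[v]`` is a tuple of coefficients (Fraction for exact work,
    float otherwise), constant term first.  Houses both rho(G) and the
    equilibrium mu(G) (whose entries are monomials gamma_i * x**b_i).
    """

    coeffs: dict
    exact: bool = True

    def degree(self, v) -> int:
        c = self.coeffs[v]
        for d in range(len(c) - 1, -1, -1):
            if c[d] != 0:
                return d
        return 0

    def evaluate(self, v, x):
        acc, xp = 0, 1
        for c in self.coeffs[v]:
            acc += c * xp
            xp *= x
        return acc

    def sum_coefficients(self):
        """Coefficient list of the sum over vertices (the normalizing
        denominator of the steady state)."""
        deg = max(len(c) for c in self.coeffs.values())
        out = [0] * deg
        for c in self.coeffs.values():
            for d, cd in enumerate(c):
                out[d] += cd
        while len(out) > 1 and out[-1] == 0:
            out.pop()
        return out

    def denominator_degree(self) -> int:
        out = self.sum_coefficients()
        return len(out) - 1


def _trim(c):
    c = list(c)
    while len(c) > 1 and c[-1] == 0:
        c.pop()
    return tuple(c)


# ---------------------------------------------------------------------------
# Spanning trees: enumeration oracle and Matrix-Tree determinants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpanningTree:
    """A spanning tree rooted at ``root``: every non-root vertex has
    exactly one outgoing edge and the undirected skeleton is acyclic."""

    edges: frozenset
    root: object


def enumerate_rooted_spanning_trees(G: LabeledGraph, root, cap: int = ENUMERATION_CAP):
    """Exhaustively enumerate the spanning trees of G rooted at ``root``.

    Brute force over one outgoing edge choice per non-root vertex,
    keeping the acyclic (root-reaching) selections.  This is the oracle
    against which the determinant route is checked; it refuses graphs
    with more than ``cap`` vertices.
    """
    if G.n > cap:
        raise ValueError(f"graph has {G.n} > {cap} vertices; enumeration capped")
    if not validate(G)["strongly_connected"]:
        raise NotStronglyConnectedError("spanning trees rooted at every vertex "
                                        "require strong connectivity")
    non_root = [v for v in G.vertices if v != root]
    choices = [G.out_edges(v) for v in non_root]
    trees = set()
    for combo in itertools.product(*choices):
        succ = {i: j for (i, j) in combo}
        ok = True
        for v in non_root:
            seen = set()
            w = v
            while w != root:
                if w in seen:
                    ok = False
                    break
                seen.add(w)
                w = succ[w]
            if not ok:
                break
        if ok:
            trees.add(SpanningTree(frozenset(combo), root))
    return trees


def _det_bareiss_int(M):
    """Exact determinant of a square integer matrix (fraction-free
    Bareiss elimination over Python ints)."""
    A = [row[:] for row in M]
    n = len(A)
    sign, prev = 1, 1
    for k in range(n - 1):
        if A[k][k] == 0:
            for r in range(k + 1, n):
                if A[r][k] != 0:
                    A[k], A[r] = A[r], A[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                A[i][j] = (A[i][j] * A[k][k] - A[i][k] * A[k][j]) // prev
            A[i][k] = 0
        prev = A[k][k]
    return sign * A[-1][-1]


def _det_fraction(M):
    """Exact determinant over Fractions by Gaussian elimination."""
    A = [[Fraction(v) for v in row] for row in M]
    n = len(A)
    det = Fraction(1)
    for k in range(n):
        piv = None
        for r in range(k, n):
            if A[r][k] != 0:
                piv = r
                break
        if piv is None:
            return Fraction(0)
        if piv != k:
            A[k], A[piv] = A[piv], A[k]
            det = -det
        det *= A[k][k]
        inv = 1 / A[k][k]
        for i in range(k + 1, n):
            if A[i][k] != 0:
                f = A[i][k] * inv
                for j in range(k, n):
                    A[i][j] -= f * A[k][j]
    return det


def _neg_laplacian_minor_exact(G: LabeledGraph, x: Fraction, drop: int):
    """-L(G)(x) with row and column ``drop`` removed, as exact Fractions."""
    n = G.n
    M = [[Fraction(0)] * n for _ in range(n)]
    for (i, j), (rate, flag) in G.edges.items():
        a, b = G.index(i), G.index(j)
        lab = Fraction(rate) * (x if flag else 1)
        M[b][a] -= lab
        M[a][a] += lab
    return [
        [M[r][c] for c in range(n) if c != drop]
        for r in range(n)
        if r != drop
    ]


def count_rooted_spanning_trees(G: LabeledGraph, root) -> int:
    """Number of spanning trees of the *structure* of G rooted at
    ``root`` (all labels treated as 1), by the Matrix-Tree theorem: the
    exact integer determinant of the Laplacian minor that deletes the
    root's row and column."""
    if not validate(G)["strongly_connected"]:
        raise NotStronglyConnectedError("tree counts require strong connectivity")
    n = G.n
    r = G.index(root)
    M = [[0] * n for _ in range(n)]
    for (i, j) in G.edges:
        a, b = G.index(i), G.index(j)
        M[b][a] -= 1
        M[a][a] += 1
    minor = [
        [M[i][j] for j in range(n) if j != r]
        for i in range(n)
        if i != r
    ]
    return _det_bareiss_int(minor)


def _rho_enumeration(G: LabeledGraph, cap: int) -> PolyVector:
    coeffs = {}
    dmax = sum(flag for (_, flag) in G.edges.values())
    for v in G.vertices:
        acc = [Fraction(0)] * (dmax + 1)
        for tree in enumerate_rooted_spanning_trees(G, v, cap=cap):
            prod, deg = Fraction(1), 0
            for (i, j) in tree.edges:
                rate, flag = G.edges[(i, j)]
                prod *= Fraction(rate)
                deg += flag
            acc[deg] += prod
        coeffs[v] = _trim(acc)
    return PolyVector(coeffs, exact=True)


def _rho_minors_exact(G: LabeledGraph) -> PolyVector:
    """Exact rho(G) as polynomials in x via Laplacian first minors
    evaluated at D+1 integer points and Lagrange interpolation, where D
    bounds the x-degree (min of: binding edges, tree size)."""
    n = G.n
    D = min(sum(flag for (_, flag) in G.edges.values()), n - 1)
    xs = [Fraction(k) for k in range(1, D + 2)]
    vals = {v: [] for v in G.vertices}
    for x in xs:
        for v in G.vertices:
            minor = _neg_laplacian_minor_exact(G, x, G.index(v))
            vals[v].append(_det_fraction(minor) if minor else Fraction(1))
    # solve the (D+1)x(D+1) Vandermonde system exactly per vertex
    V = [[x ** d for d in range(D + 1)] for x in xs]
    coeffs = {}
    for v in G.vertices:
        sol = _solve_fraction(V, vals[v])
        coeffs[v] = _trim(sol)
    return PolyVector(coeffs, exact=True)


def _solve_fraction(A, b):
    n = len(A)
    M = [[Fraction(A[i][j]) for j in range(n)] + [Fraction(b[i])] for i in range(n)]
    for k in range(n):
        piv = next(r for r in range(k, n) if M[r][k] != 0)
        M[k], M[piv] = M[piv], M[k]
        inv = 1 / M[k][k]
        M[k] = [v * inv for v in M[k]]
        for r in range(n):
            if r != k and M[r][k] != 0:
                f = M[r][k]
                M[r] = [vr - f * vk for vr, vk in zip(M[r], M[k])]
    return [M[i][n] for i in range(n)]


def rho(G: LabeledGraph, mode: str = "minors", x=None, cap: int = ENUMERATION_CAP):
    """The Matrix-Tree kernel vector rho(G).

    mode='enumeration'
        Exact PolyVector by brute-force spanning-tree enumeration
        (oracle; vertex count capped).
    mode='minors'
        Exact PolyVector via first minors of the Laplacian — determinant
        of -L with vertex i's row and column deleted equals rho_i —
        interpolated over x; no enumeration, any modest size.
    mode='numeric'
        Per-vertex floats at a fixed ``x`` via dense determinants.
    """
    if not validate(G)["strongly_connected"]:
        raise NotStronglyConnectedError("rho requires strong connectivity")
    if mode == "enumeration":
        return _rho_enumeration(G, cap)
    if mode == "minors":
        return _rho_minors_exact(G)
    if mode == "numeric":
        if x is None or x <= 0:
            raise ValueError("numeric mode needs x > 0")
        return _rho_numeric(G, x)
    raise ValueError(f"unknown mode {mode!r}")


def _rho_numeric(G: LabeledGraph, x) -> np.ndarray:
    L = laplacian(G, x)
    n = G.n
    out = np.empty(n)
    M = -L
    for i in range(n):
        idx = [j for j in range(n) if j != i]
        out[i] = np.linalg.det(M[np.ix_(idx, idx)]) if n > 1 else 1.0
    return out


def steady_state(G: LabeledGraph, x) -> np.ndarray:
    """Steady-state probabilities at input concentration x, ordered as
    G.vertices: rho(G) normalized to sum 1."""
    r = _rho_numeric(G, x)
    total = r.sum()
    if total <= 0 or not np.all(r > 0):
        # fall back to exact arithmetic for ill-conditioned label spreads
        pv = _rho_minors_exact(G)
        vals = np.array([float(pv.evaluate(v, Fraction(x))) for v in G.vertices])
        return vals / vals.sum()
    return r / total


# ---------------------------------------------------------------------------
# Thermodynamic equilibrium: cycle condition, mu vector, path entropy
# ---------------------------------------------------------------------------

def _reversible_spanning_tree(G: LabeledGraph):
    """BFS spanning tree over reversible pairs: parent map and order."""
    root = G.vertices[0]
    parent = {root: None}
    order = [root]
    adj = {v: [] for v in G.vertices}
    for (i, j) in G.edges:
        if (j, i) in G.edges:
            adj[i].append(j)
    queue = [root]
    while queue:
        v = queue.pop(0)
        for w in sorted(adj[v], key=str):
            if w not in parent:
                parent[w] = v
                order.append(w)
                queue.append(w)
    if len(parent) != G.n:
        raise CycleConditionError(
            "graph is not connected through reversible edge pairs"
        )
    return parent, order


def _log_ratio(G: LabeledGraph, i, j) -> float:
    """log(rate(i->j) / rate(j->i)); x factors cancel on cycles because
    net binding around a cycle is zero, so they are omitted here."""
    fwd, _ = G.edges[(i, j)]
    bwd, _ = G.edges[(j, i)]
    return math.log(float(fwd)) - math.log(float(bwd))


def cycle_condition_satisfied(G: LabeledGraph, tol: float = 1e-9) -> bool:
    """True iff |log mu(P)| <= tol for every cycle in a fundamental
    cycle basis (spanning-tree complement over reversible pairs) — the
    detailed-balance / zero-entropy-production diagnostic."""
    if not validate(G)["reversible"]:
        raise CycleConditionError("cycle condition is defined for reversible graphs")
    parent, _ = _reversible_spanning_tree(G)
    # potential phi(v) = log mu along the tree path from the root
    phi = {}
    for v in G.vertices:
        if v in phi:
            continue
        chain = []
        w = v
        while w not in phi and parent[w] is not None:
            chain.append(w)
            w = parent[w]
        base = phi.get(w, 0.0)
        for u in reversed(chain):
            base = base + _log_ratio(G, parent[u], u)
            phi[u] = base
    phi[G.vertices[0]] = 0.0
    for (i, j) in G.reversible_pairs():
        if parent.get(j) == i or parent.get(i) == j:
            continue
        circ = phi[i] + _log_ratio(G, i, j) - phi[j]
        if abs(circ) > tol:
            return False
    return True


def mu_vector(G: LabeledGraph, reference=None, tol: float = 1e-9) -> PolyVector:
    """Equilibrium weight vector mu(G): the path label-ratio product
    from the reference vertex to each vertex.

    For a graph satisfying the cycle condition the result is
    path-independent, and each entry is the monomial gamma_i * x**b_i
    where b_i = |binding_pattern(i)| (each net input binding along the
    path contributes one factor of x).  The reference must be a vertex
    with no input site bound, so mu_reference = 1.
    """
    if not cycle_condition_satisfied(G, tol=tol):
        raise CycleConditionError("cycle condition violated; use rho instead")
    if reference is None:
        empties = [v for v in G.vertices if not G.binding_pattern[v]]
        if not empties:
            raise CycleConditionError("no vertex with empty binding pattern")
        reference = empties[0]
    if G.binding_pattern[reference]:
        raise CycleConditionError("reference vertex must have an empty pattern")
    exact = all(isinstance(r, (int, Fraction)) for (r, _) in G.edges.values())
    one = Fraction(1) if exact else 1.0
    parent, order = _reversible_spanning_tree(G)
    # re-root the BFS tree at the reference by walking gamma along tree edges
    gamma = {reference: one}
    bdeg = {reference: 0}
    changed = True
    while changed:
        changed = False
        # walk tree edges from known to unknown in both directions
        for v in order:
            p = parent[v]
            if p is None:
                continue
            for a, b in ((p, v), (v, p)):
                if a in gamma and b not in gamma:
                    fwd, ff = G.edges[(a, b)]
                    bwd, bf = G.edges[(b, a)]
                    g = gamma[a] * fwd / bwd if exact else gamma[a] * float(fwd) / float(bwd)
                    gamma[b] = g
                    bdeg[b] = bdeg[a] + ff - bf
                    changed = True
    coeffs = {}
    for v in G.vertices:
        b = bdeg[v]
        if b != len(G.binding_pattern[v]):
            raise CycleConditionError(
                f"net bindings along path to {v!r} ({b}) disagree with its "
                f"binding pattern size ({len(G.binding_pattern[v])})"
            )
        c = [Fraction(0) if exact else 0.0] * (b + 1)
        c[b] = gamma[v]
        coeffs[v] = tuple(c)
    return PolyVector(coeffs, exact=exact)


def equilibrium_steady_state(G: LabeledGraph, x, reference=None) -> np.ndarray:
    """Steady state at equilibrium via mu(G) normalization (the
    grand-canonical partition function route)."""
    mu = mu_vector(G, reference=reference)
    vals = np.array([float(mu.evaluate(v, x)) for v in G.vertices])
    return vals / vals.sum()


def path_entropy(G: LabeledGraph, path, x=1.0) -> float:
    """log mu(P) along a path of reversible edges: the entropy generated
    along P.  Additive under concatenation, antisymmetric under
    reversal, and zero over cycles at thermodynamic equilibrium."""
    total = 0.0
    lx = math.log(float(x))
    for i, j in zip(path[:-1], path[1:]):
        if (i, j) not in G.edges or (j, i) not in G.edges:
            raise ValueError(f"path step {i!r}->{j!r} is not a reversible edge pair")
        (fr, ff), (br, bf) = G.edges[(i, j)], G.edges[(j, i)]
        total += math.log(float(fr)) - math.log(float(br)) + (ff - bf) * lx
    return total
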