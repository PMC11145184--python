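"""Labeled-digraph data model for linear-framework Markov processes.

A linear-framework graph has vertices that represent molecular states,
directed edges that represent transitions, and positive edge labels that
are transition rates (time^-1).  The input ligand, at concentration ``x``,
binds with mass-action first-order kinetics, so an edge at which one
molecule of the input binds carries the effective label ``rate * x``;
every other edge carries just its rate.  Concentrations of any other
ligands are folded into the rate constants, which are held fixed while
``x`` is varied quasi-statically.

Each vertex carries a *binding pattern*: the subset of the ``m`` input
binding sites that are occupied in that state.  Any further molecular
features (conformations, coregulators, other ligands) are represented
implicitly as distinct vertices sharing a binding pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Number
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

Pattern = frozenset  # frozenset of int site indices, 1-based


class GraphValidationError(ValueError):
    """Raised when edge records or binding patterns are inconsistent."""


def pattern_name(sites: Iterable[int]) -> str:
    """Canonical vertex name for a binding pattern: '0' for the empty
    pattern, otherwise the sorted site indices joined by '+'."""
    s = sorted(sites)
    return "+".join(str(i) for i in s) if s else "0"


@dataclass(frozen=True)
class LabeledGraph:
    """Immutable labeled digraph with per-vertex input-binding patterns.

    Parameters
    ----------
    vertices : tuple of str
        Vertex identifiers, in a fixed order used by all matrix routines.
    binding_pattern : mapping vertex -> frozenset of int
        Input sites bound in each state.
    edges : mapping (source, target) -> (rate, binds_input)
        ``rate`` is a positive number (int, float or Fraction);
        ``binds_input`` is 1 iff traversing the edge binds one input
        molecule, so the effective label is ``rate * x**binds_input``.
    n_sites : int
        Number of input binding sites ``m``.
    """

    vertices: tuple
    binding_pattern: dict
    edges: dict
    n_sites: int
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {v: i for i, v in enumerate(self.vertices)}
        )

    @property
    def n(self) -> int:
        return len(self.vertices)

    def index(self, v) -> int:
        return self._index[v]

    def out_edges(self, v):
        return [(i, j) for (i, j) in self.edges if i == v]

    def label(self, i, j, x):
        """Effective label ell(i->j) = rate * x**binds_input."""
        rate, flag = self.edges[(i, j)]
        return rate * x if flag else rate

    def has_reverse(self, i, j) -> bool:
        return (j, i) in self.edges

    def reversible_pairs(self):
        """Unordered reversible pairs {i, j}, each reported once."""
        seen = set()
        for (i, j) in self.edges:
            if (j, i) in self.edges and (j, i) not in seen:
                seen.add((i, j))
        return sorted(seen)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for (i, j), (rate, flag) in self.edges.items():
            g.add_edge(i, j, rate=rate, binds_input=flag)
        return g


def build_graph(
    edge_records: Sequence[tuple],
    patterns: Mapping,
    n_sites: int | None = None,
) -> LabeledGraph:
    """Validate edge records and binding patterns into a LabeledGraph.

    ``edge_records`` are ``(source, target, rate, binds_input)`` tuples;
    ``patterns`` maps every vertex to an iterable of bound site indices.
    ``n_sites`` defaults to the largest site index appearing in any
    pattern (0 if none).

    Raises
    ------
    GraphValidationError
        For non-positive rates, flags outside {0, 1}, duplicate edges,
        self-loops, unknown vertices, or a binding edge whose endpoint
        patterns do not differ by exactly one newly bound site.
    """
    pat = {v: frozenset(int(s) for s in sites) for v, sites in patterns.items()}
    if n_sites is None:
        n_sites = max((max(s) for s in pat.values() if s), default=0)
    for v, s in pat.items():
        if any(i < 1 or i > n_sites for i in s):
            raise GraphValidationError(
                f"vertex {v!r}: sites {sorted(s)} outside 1..{n_sites}"
            )
    edges = {}
    for rec in edge_records:
        i, j, rate, flag = rec
        if i not in pat or j not in pat:
            raise GraphValidationError(f"edge {i!r}->{j!r}: unknown vertex")
        if i == j:
            raise GraphValidationError(f"self-loop at {i!r}")
        if not isinstance(rate, Number) or rate <= 0:
            raise GraphValidationError(f"edge {i!r}->{j!r}: rate {rate!r} not > 0")
        flag = int(flag)
        if flag not in (0, 1):
            raise GraphValidationError(
                f"edge {i!r}->{j!r}: binds_input must be 0 or 1 (first-order binding)"
            )
        if (i, j) in edges:
            raise GraphValidationError(f"duplicate edge {i!r}->{j!r}")
        if flag == 1:
            gained = pat[j] - pat[i]
            lost = pat[i] - pat[j]
            if len(gained) != 1 or lost:
                raise GraphValidationError(
                    f"binding edge {i!r}->{j!r}: patterns must differ by "
                    f"exactly one newly bound site"
                )
        edges[(i, j)] = (rate, flag)
    vertices = tuple(sorted(pat, key=str))
    return LabeledGraph(vertices, pat, edges, n_sites)


def _hypercube_edge_iter(m: int):
    """All directed binding/unbinding edges of the hypercube C_m, as
    (source_pattern, target_pattern, binds_input)."""
    from itertools import combinations

    subsets = [frozenset(c) for k in range(m + 1) for c in combinations(range(1, m + 1), k)]
    for s in subsets:
        for site in range(1, m + 1):
            if site not in s:
                t = s | {site}
                yield s, t, 1
                yield t, s, 0


def build_hypercube(m: int, rates: Mapping | None = None, default_rate=1.0) -> LabeledGraph:
    """The hypercube graph C_m: 2**m binding patterns of m sites, with a
    reversible edge pair between patterns differing in one site; the
    binding direction is flagged ``binds_input = 1``.

    ``rates`` may supply per-edge rates keyed by ``(source_name,
    target_name)``; missing edges fall back to ``default_rate`` (pass
    ``default_rate=None`` to require an explicit rate for every edge).
    """
    if m < 1:
        raise GraphValidationError("m must be >= 1")
    rates = dict(rates or {})
    records, patterns = [], {}
    for s, t, flag in _hypercube_edge_iter(m):
        u, v = pattern_name(s), pattern_name(t)
        patterns[u], patterns[v] = s, t
        rate = rates.get((u, v), default_rate)
        if rate is None:
            raise GraphValidationError(f"no rate supplied for edge {u}->{v}")
        records.append((u, v, rate, flag))
    return build_graph(records, patterns, n_sites=m)


def build_hypercube_substructure(
    m: int,
    removed_vertices: Iterable = (),
    removed_edge_pairs: Iterable = (),
    rates: Mapping | None = None,
    default_rate=1.0,
) -> LabeledGraph:
    """Substructure of C_m with binding patterns removed (mutual
    exclusion) and/or reversible edge pairs removed (ordered binding).

    ``removed_vertices`` are patterns (iterables of sites); each entry of
    ``removed_edge_pairs`` is a pair of patterns whose two directed edges
    are both deleted.  The remaining graph must stay strongly connected
    and reversible.
    """
    gone_v = {frozenset(v) for v in removed_vertices}
    gone_e = set()
    for a, b in removed_edge_pairs:
        a, b = frozenset(a), frozenset(b)
        gone_e.add((a, b))
        gone_e.add((b, a))
    rates = dict(rates or {})
    from itertools import combinations

    patterns = {
        pattern_name(s): s
        for k in range(m + 1)
        for c in combinations(range(1, m + 1), k)
        if (s := frozenset(c)) not in gone_v
    }
    records = []
    for s, t, flag in _hypercube_edge_iter(m):
        if s in gone_v or t in gone_v or (s, t) in gone_e:
            continue
        u, v = pattern_name(s), pattern_name(t)
        rate = rates.get((u, v), default_rate)
        if rate is None:
            raise GraphValidationError(f"no rate supplied for edge {u}->{v}")
        records.append((u, v, rate, flag))
    if not records:
        raise GraphValidationError("removal left no edges")
    G = build_graph(records, patterns, n_sites=m)
    rep = validate(G)
    if not rep["strongly_connected"] or not rep["reversible"]:
        raise GraphValidationError(
            "removal breaks strong connectivity or reversibility"
        )
    return G


def laplacian(G: LabeledGraph, x) -> np.ndarray:
    """Laplacian L(G) of the master equation du/dt = L(G) u at input
    concentration x: entry (j, i) = ell(i->j) for i != j, and column i's
    diagonal entry is minus the sum of i's outgoing labels, so every
    column sums to zero (probability conservation)."""
    if x <= 0:
        raise ValueError("x must be > 0")
    n = G.n
    L = np.zeros((n, n))
    for (i, j), (rate, flag) in G.edges.items():
        a, b = G.index(i), G.index(j)
        lab = float(rate) * (x if flag else 1.0)
        L[b, a] += lab
        L[a, a] -= lab
    return L


def validate(G: LabeledGraph) -> dict:
    """Report strong connectivity (unique steady state) and
    reversibility (every edge has its reverse)."""
    g = G.to_networkx()
    return {
        "strongly_connected": G.n > 0 and nx.is_strongly_connected(g),
        "reversible": all((j, i) in G.edges for (i, j) in G.edges),
    }
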