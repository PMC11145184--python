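from fractions import Fraction

import numpy as np
import pytest

import hillbarrier as hb


@pytest.fixture
def k2():
    """Minimal reversible two-state graph: rates a=2 (1->2), b=1 (2->1)."""
    return hb.build_graph(
        [("1", "2", 2.0, 0), ("2", "1", 1.0, 0)], {"1": [], "2": []}
    )


@pytest.fixture
def c1():
    """One binding site: on-rate 1 (flagged), off-rate 1."""
    return hb.build_hypercube(1)


@pytest.fixture
def triangle():
    """Reversible triangle, all rates 1 (cycle condition holds)."""
    recs = []
    for i, j in [("a", "b"), ("b", "c"), ("c", "a")]:
        recs += [(i, j, 1.0, 0), (j, i, 1.0, 0)]
    return hb.build_graph(recs, {"a": [], "b": [], "c": []})


def rationalize(G, rng):
    """Replace every rate by a random exact Fraction (same structure)."""
    recs = [
        (i, j, Fraction(int(rng.integers(1, 13)), int(rng.integers(1, 13))), flag)
        for (i, j), (_, flag) in G.edges.items()
    ]
    return hb.build_graph(
        recs, {v: G.binding_pattern[v] for v in G.vertices}, n_sites=G.n_sites
    )


X_GRID = np.logspace(-3, 3, 7)  # six decades of input concentration
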