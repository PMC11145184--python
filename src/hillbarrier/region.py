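"""Occupancy-grid estimation of position-steepness regions.

The (p, s) plane is divided into square cells (side 0.005 by default).
A region estimate starts from a large batch of random parameter draws
and is then grown by a two-phase mutation search over the *working
boundary* — the occupied cells with an empty neighbor directly above,
below, left or right:

* phase 1: the archived parameter set of each boundary cell is mutated
  repeatedly until a mutant's (p, s) point lands in an empty cell;
* phase 2: a target point is placed outside the boundary (outward from
  the cell along its empty-neighbor direction) and mutations are kept
  greedily whenever they reduce the distance to the target, which pulls
  the search out of deep valleys phase 1 cannot escape.

The run converges when no new boundary cell has appeared for a set
number of consecutive boundary-cell iterations (default 1,500).

Samplers are provided for the three parameterizations the analysis
needs: direct equilibrium coefficient vectors (the universal region
Omega_m, via the realizability of every constrained coefficient
vector), equilibrium hypercube vertex weights, and unconstrained
nonequilibrium hypercube edge labels — the last of which escapes the
Hill barrier H_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .graph_core import build_hypercube
from .response import RationalResponse, fractional_saturation_weights
from .sharpness import DegenerateResponseError, SharpnessPoint, hill_point, position_steepness
from .steady_state import rho

DEFAULT_CELL_SIZE = 0.005
DEFAULT_STAGNATION_LIMIT = 1500
DEFAULT_MUTATION_SCALE = 0.25   # log10 half-width of a mutation step
DEFAULT_PHASE_ATTEMPTS = 200


def cell_of(p: float, s: float, cell_size: float) -> tuple[int, int]:
    return (math.floor(p / cell_size), math.floor(s / cell_size))


def working_boundary(occupancy, cell_size: float = DEFAULT_CELL_SIZE) -> set:
    """Occupied cells with an empty immediate neighbor in their row or
    column (4-neighborhood)."""
    cells = set(occupancy)
    return {
        (i, j)
        for (i, j) in cells
        if any(n not in cells for n in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)))
    }


# ---------------------------------------------------------------------------
# Samplers: parameter set -> (p, s)
# ---------------------------------------------------------------------------

class EquilibriumCoefficientSampler:
    """Direct sampler of the universal equilibrium rational form.

    Parameters are the 2(l+1) base-10 logarithms (beta first, then
    alpha); draws put log10(beta_i) ~ U(-a, a) and log10(alpha_i) ~
    U(-a, log10(beta_i)).  Mutation multiplies every coefficient by
    10^eps with eps ~ U(-delta, delta), then re-clips beta to the
    sampling box and alpha to [-a, log10(beta_i)] so the equilibrium
    constraints are preserved.
    """

    def __init__(self, l: int, a: float, delta: float = DEFAULT_MUTATION_SCALE):
        if l < 1 or a <= 0:
            raise ValueError("need l >= 1 and a > 0")
        self.l, self.a, self.delta = int(l), float(a), float(delta)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        lb = rng.uniform(-self.a, self.a, self.l + 1)
        la = rng.uniform(-self.a, lb)
        return np.concatenate([lb, la])

    def mutate(self, params: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = params + rng.uniform(-self.delta, self.delta, params.size)
        k = self.l + 1
        out[:k] = np.clip(out[:k], -self.a, self.a)
        out[k:] = np.clip(out[k:], -self.a, out[:k])
        return out

    def point(self, params: np.ndarray):
        k = self.l + 1
        r = RationalResponse(tuple(10.0 ** params[k:]), tuple(10.0 ** params[:k]))
        try:
            sp = position_steepness(r)
        except DegenerateResponseError:
            return None
        return sp


class UnconstrainedCoefficientSampler(EquilibriumCoefficientSampler):
    """Coefficient sampler without the alpha_i <= beta_i constraint
    (both exponents uniform on [-a, a]); its points can leave the
    universal equilibrium region."""

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-self.a, self.a, 2 * (self.l + 1))

    def mutate(self, params: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = params + rng.uniform(-self.delta, self.delta, params.size)
        return np.clip(out, -self.a, self.a)


class _HypercubeSamplerBase:
    def __init__(self, m: int, a: float, delta: float = DEFAULT_MUTATION_SCALE):
        if m < 2 or a <= 0:
            raise ValueError("need m >= 2 and a > 0")
        self.m, self.a, self.delta = int(m), float(a), float(delta)
        self.structure = build_hypercube(m)
        self.weights = fractional_saturation_weights(self.structure)
        self.edge_order = sorted(self.structure.edges)

    def mutate(self, params: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = params + rng.uniform(-self.delta, self.delta, params.size)
        return np.clip(out, -self.a, self.a)

    def _ps_from_polys(self, alpha, beta):
        try:
            return position_steepness(RationalResponse(tuple(alpha), tuple(beta)))
        except DegenerateResponseError:
            return None


class NonequilibriumHypercubeSampler(_HypercubeSamplerBase):
    """Fractional saturation on the hypercube C_m with every directed
    edge label drawn log-uniform on [-a, a] — generically away from
    thermodynamic equilibrium (the cycle condition fails).  The
    response's rational coefficients are recovered exactly from the
    Matrix-Tree polynomials, whose denominator degree (2^m - 1 binding
    edges in a spanning tree of C_2, etc.) exceeds m."""

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-self.a, self.a, len(self.edge_order))

    def point(self, params: np.ndarray):
        G = build_hypercube(
            self.m,
            rates={e: float(10.0 ** v) for e, v in zip(self.edge_order, params)},
        )
        pv = rho(G, mode="minors")
        deg = pv.denominator_degree()
        beta = np.zeros(deg + 1)
        alpha = np.zeros(deg + 1)
        for v in G.vertices:
            lam = self.weights[v]
            for d, c in enumerate(pv.coeffs[v]):
                cf = float(c)
                beta[d] += cf
                alpha[d] += lam * cf
        if beta[-1] <= 0 or beta[0] <= 0:
            return None
        return self._ps_from_polys(alpha, beta)


class EquilibriumHypercubeSampler(_HypercubeSamplerBase):
    """Fractional saturation on C_m with labels constrained to the
    cycle condition: vertex weights log10(gamma_S) ~ U(-a, a) determine
    every label ratio, so the steady state is the Boltzmann-like
    mu-vector gamma_S x^{|S|}."""

    def __init__(self, m: int, a: float, delta: float = DEFAULT_MUTATION_SCALE):
        super().__init__(m, a, delta)
        self.vertex_order = list(self.structure.vertices)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-self.a, self.a, len(self.vertex_order))

    def point(self, params: np.ndarray):
        G = self.structure
        beta = np.zeros(self.m + 1)
        alpha = np.zeros(self.m + 1)
        for v, lg in zip(self.vertex_order, params):
            gamma = 10.0 ** lg
            b = len(G.binding_pattern[v])
            beta[b] += gamma
            alpha[b] += self.weights[v] * gamma
        return self._ps_from_polys(alpha, beta)


# ---------------------------------------------------------------------------
# Region estimation
# ---------------------------------------------------------------------------

@dataclass
class RegionEstimate:
    """Result of a boundary-exploration run."""

    cell_size: float
    occupancy: dict                 # cell -> sample count
    boundary: set                   # final working boundary
    archive: dict                   # boundary cell -> generating parameters
    hyperparams: dict
    trace: list = field(default_factory=list)  # new boundary cells per sweep
    iterations: int = 0             # boundary-cell iterations performed
    n_failures: int = 0             # draws with no finite (p, s)
    n_outside: int = 0              # points falling outside the window

    def occupied_cells(self) -> set:
        return set(self.occupancy)

    def cell_centers(self) -> np.ndarray:
        c = self.cell_size
        return np.array([[(i + 0.5) * c, (j + 0.5) * c] for (i, j) in self.occupancy])


def _outward_target(cell, cells, cell_size, reach=3.0):
    i, j = cell
    d = np.zeros(2)
    for (ni, nj), v in (
        ((i + 1, j), (1.0, 0.0)),
        ((i - 1, j), (-1.0, 0.0)),
        ((i, j + 1), (0.0, 1.0)),
        ((i, j - 1), (0.0, -1.0)),
    ):
        if (ni, nj) not in cells:
            d += v
    norm = np.hypot(*d)
    if norm == 0.0:
        return None
    center = np.array([(i + 0.5) * cell_size, (j + 0.5) * cell_size])
    return center + (reach * cell_size / norm) * d


def estimate_region(
    sampler,
    n_init: int,
    rng: np.random.Generator,
    cell_size: float = DEFAULT_CELL_SIZE,
    stagnation_limit: int = DEFAULT_STAGNATION_LIMIT,
    phase1_attempts: int = DEFAULT_PHASE_ATTEMPTS,
    phase2_attempts: int = DEFAULT_PHASE_ATTEMPTS,
    window: tuple[float, float] = (1.25, 1.25),
) -> RegionEstimate:
    """Estimate the (p, s) region reachable by ``sampler``.

    ``sampler`` must provide ``draw(rng) -> params``,
    ``mutate(params, rng) -> params`` and ``point(params) ->
    SharpnessPoint | None`` (None flags a degenerate parameter set).
    Runs ``n_init`` seeding draws, then alternates the two mutation
    phases over the working boundary until no new boundary cell has
    appeared for ``stagnation_limit`` consecutive boundary-cell
    iterations.  Fully reproducible from ``rng``'s seed; occupancy only
    ever grows.

    ``window = (p_max, s_max)`` bounds the tracked portion of the
    plane.  The (p, s) regions have wings that taper toward both axes
    with, in particular, unbounded steepness as the position goes to 0,
    so an unwindowed boundary chase would discover new wing cells
    forever; the window fixes the area of interest around the Hill
    line (points outside it are counted but not gridded).
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    occupancy: dict = {}
    archive: dict = {}
    n_fail = 0
    n_outside = 0
    new_boundary_flag = [False]

    def record(params):
        nonlocal n_outside
        sp = sampler.point(params)
        if sp is None:
            return None, False
        if sp.p > window[0] or sp.s > window[1]:
            n_outside += 1
            return None, False
        cell = cell_of(sp.p, sp.s, cell_size)
        fresh = cell not in occupancy
        occupancy[cell] = occupancy.get(cell, 0) + 1
        if fresh:
            archive[cell] = (np.array(params, copy=True), sp)
            i, j = cell
            if any(
                nb not in occupancy
                for nb in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1))
            ):
                new_boundary_flag[0] = True
        return (cell, sp), fresh

    for _ in range(n_init):
        res, _ = record(sampler.draw(rng))
        if res is None:
            n_fail += 1
    if not occupancy:
        raise RuntimeError("every seeding draw failed to produce a (p, s) point")

    stagnation = 0
    iterations = 0
    trace = []
    while stagnation < stagnation_limit:
        boundary = working_boundary(occupancy, cell_size)
        sweep_new = 0
        for cell in sorted(boundary):
            if stagnation >= stagnation_limit:
                break
            new_boundary_flag[0] = False
            params0, sp0 = archive[cell]
            # phase 1: mutate until an empty cell is hit
            for _ in range(phase1_attempts):
                res, fresh = record(sampler.mutate(params0, rng))
                if fresh:
                    break
            # phase 2: chase a target placed outside the boundary
            target = _outward_target(cell, occupancy, cell_size)
            if target is not None:
                cur, cur_d = params0, float(
                    np.hypot(sp0.p - target[0], sp0.s - target[1])
                )
                for _ in range(phase2_attempts):
                    if cur_d < 0.5 * cell_size:
                        break
                    cand = sampler.mutate(cur, rng)
                    res, fresh = record(cand)
                    if res is None:
                        continue
                    _, sp = res
                    d = float(np.hypot(sp.p - target[0], sp.s - target[1]))
                    if d < cur_d:
                        cur, cur_d = cand, d
            iterations += 1
            if new_boundary_flag[0]:
                sweep_new += 1
                stagnation = 0
            else:
                stagnation += 1
        trace.append(sweep_new)
        if not boundary:
            break
    final_boundary = working_boundary(occupancy, cell_size)
    return RegionEstimate(
        cell_size=cell_size,
        occupancy=occupancy,
        boundary=final_boundary,
        archive={c: archive[c][0] for c in final_boundary if c in archive},
        hyperparams={
            "n_init": n_init,
            "stagnation_limit": stagnation_limit,
            "phase1_attempts": phase1_attempts,
            "phase2_attempts": phase2_attempts,
            "mutation_scale": getattr(sampler, "delta", None),
            "a": getattr(sampler, "a", None),
            "l": getattr(sampler, "l", None),
            "m": getattr(sampler, "m", None),
            "window": tuple(window),
        },
        trace=trace,
        iterations=iterations,
        n_failures=n_fail,
        n_outside=n_outside,
    )


# ---------------------------------------------------------------------------
# Point clouds and the Hill barrier test
# ---------------------------------------------------------------------------

def _sample_cloud(sampler, n: int, rng: np.random.Generator):
    out = []
    for _ in range(n):
        params = sampler.draw(rng)
        sp = sampler.point(params)
        if sp is not None:
            out.append((sp, params))
    return out


def nonequilibrium_ps_sample(m: int, a: float, n: int, rng: np.random.Generator):
    """n fractional-saturation (p, s) points of C_m with log-uniform
    unconstrained edge labels (generically nonequilibrium), each with
    its generating parameter vector."""
    return _sample_cloud(NonequilibriumHypercubeSampler(m, a), n, rng)


def equilibrium_hypercube_ps_sample(m: int, a: float, n: int, rng: np.random.Generator):
    """Matched equilibrium control: same structure and output, labels
    projected onto the cycle-condition parameterization (vertex
    weights)."""
    return _sample_cloud(EquilibriumHypercubeSampler(m, a), n, rng)


def exceeds_hill_barrier(points, h: float):
    """Points strictly beyond the Hill function H_h in *both*
    coordinates: p > p(H_h) and s > s(H_h).  Accepts SharpnessPoints,
    (SharpnessPoint, params) pairs, or bare (p, s) tuples."""
    ph, sh = hill_point(h)
    out = []
    for item in points:
        sp = item[0] if isinstance(item, tuple) and isinstance(item[0], SharpnessPoint) else item
        p, s = (sp.p, sp.s) if isinstance(sp, SharpnessPoint) else (sp[0], sp[1])
        if p > ph and s > sh:
            out.append(item)
    return out
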