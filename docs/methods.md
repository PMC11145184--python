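# Methods

## Model class and assumptions

A model is a finite, strongly connected, labeled digraph: vertices are
molecular states, directed edges are transitions, and each edge label is a
positive first-order rate constant (time⁻¹). The input ligand, at free
concentration *x*, binds with mass-action first-order kinetics, so an edge at
which one input molecule binds carries the effective label *rate · x*;
unbinding and all other transitions are zeroth order in *x*. Two standing
assumptions are hard-wired:

- **first-order binding** — an edge binds at most one input molecule
  (`binds_input ∈ {0, 1}`; higher multiplicities are rejected at
  construction);
- **reservoir conditions** — binding does not deplete the free input
  concentration, and all other ligand concentrations are constant and folded
  into the rate constants.

Each vertex carries a *binding pattern*, the subset of the *m* input sites
occupied in that state. Any further molecular detail (conformations,
coregulators, other ligands) is represented implicitly as additional vertices
sharing a binding pattern; nothing in the coarse-graining or response theory
needs those features to be named.

*x* is treated quasi-statically: every evaluation is a steady-state
evaluation at fixed *x*. No transient dynamics are solved beyond exposing the
Laplacian of the master equation du/dt = L(G)·u.

## Steady states: two routes and their numerics

**Matrix-Tree route (general).** ρ_i(G) is the sum over spanning trees rooted
at *i* of the product of edge labels; the steady state is ρ normalized.
Three evaluators are provided:

- brute-force tree enumeration (graphs ≤ 10 vertices), exact over rationals —
  the oracle;
- first minors of the Laplacian: ρ_i = det(−L) with row and column *i*
  deleted. The exact variant evaluates the minor determinants at D+1 integer
  concentrations (D = an upper bound on the x-degree) with Fraction
  arithmetic and interpolates the polynomial coefficients, avoiding both tree
  enumeration and symbolic determinant expansion;
- float determinants at fixed *x* for sampling workloads.

Integer tree *counts* use fraction-free Bareiss elimination, so results like
the 16-vertex hypercube count are bit-exact.

**Equilibrium route.** When the cycle condition holds (|log μ| ≤ 1e−9 on
every fundamental cycle of reversible pairs; the tolerance is on log μ for
scale symmetry), path weights from an unbound reference vertex give
μ_i = γ_i x^{b_i} with *b_i* the number of bound sites — the grand-canonical
Boltzmann weights. The two routes agree to ~1e−13 on well-posed graphs; the
package prefers the μ route where equilibrium is established (e.g. in the
conditional probabilities χ), because evaluating a positive monomial sum is
perfectly conditioned while float determinants lose ~3 digits over wide label
spreads.

## Coarse-graining

Vertices are partitioned by binding pattern. The coarse graph C(G) has an
edge w→z wherever some fine edge crosses the blocks, with label
ℓ(w→z) = Q · Σ_{j∈z} ρ_j(G) evaluated at the current *x* (the target-block
sum alone; this is the labeling under which detailed balance on C(G) gives
coarse steady states proportional to block weights). Q is fixed to 1 and
exposed only to demonstrate its irrelevance. C(G) then satisfies the cycle
condition by construction — even when G does not — and its steady state
equals the block sums of G's, which the package verifies to < 1e−10 rather
than assumes. Coarse-graining is a steady-state construction only; no claim
is made about the dynamics of C(G), and patterns never reached by G simply do
not appear (C(G) is a substructure of the hypercube C_m).

## Sharpness measures

For a response r with infimum m(r) and supremum M(r) over [0, ∞), the
normalization point x₀.₅ is the smallest strictly positive solution of
r(x) = (m+M)/2, and q(y) = r(y·x₀.₅). Steepness s is the global maximum of
|dq/dy|, position p the smallest maximizer; both are dimensionless and
invariant under x → c·x.

For rational responses every extremum and crossing is a real root of an
explicit polynomial (A′B − AB′ for critical points, its derivative-numerator
analogue for slope extrema, A − hB for the half-crossing), so the global
optimizations reduce to root finding:

- roots come from companion-matrix eigenvalues (closed form for quadratics)
  with an imaginary-part tolerance of 1e−8 relative for accepting a root as
  real, then 3 Newton polish steps (companion eigenvalues carry ~1e−9
  relative error when roots span many decades);
- before any root finding the input scale is rebalanced by
  c₀ = (β₀/β_l)^{1/l}, which position/steepness invariance makes free and
  which keeps the polynomial coefficients well scaled however the caller
  scaled *x*;
- maximizer ties are broken toward the smallest y within 1e−9 relative of the
  maximum slope; a maximizer at y = 0 is legitimate (p = 0, e.g. H₁) and
  populates the region's wings;
- a response with M − m ≤ 1e−12·max(1, |M|) is reported as degenerate
  (no half-point), and samplers treat such parameter sets as flagged
  failures;
- if r(0) equals the half-value to 1e−12 of the coefficient scale, the root
  at zero is deflated and the next positive crossing is returned, so x₀.₅ is
  always strictly positive.

A second, independent evaluator (`position_steepness_numeric` /
`position_steepness_grid`) searches a dense grid — the union of a
compactified-uniform grid y = t/(1−t) and a log grid down to 1e−9 — with
Brent refinement, optionally polishing the slope maximizer by root-finding on
an analytic second derivative. It serves as the cross-check oracle for the
root-isolation route and as the evaluator for non-rational responses such as
Hill functions with non-integer coefficient. Its supremum estimates approach
limits at infinity only up to the grid cap, so agreement with the exact route
is asserted in relative terms for wing-type responses.

Closed forms for the Hill family: for h > 1 the slope of H_h is maximal where
y^h = (h−1)/(h+1), giving p = ((h−1)/(h+1))^{1/h} and
s = h·p^{h−1}/(1 + (h−1)/(h+1))²; H₁ has (p, s) = (0, 1); for h < 1 the slope
diverges at 0.

## Samplers and what they emulate

**Equilibrium coefficient sampler** (the universal-region workhorse): every
constrained coefficient vector (β_i > 0, 0 ≤ α_i ≤ β_i) is realizable by some
equilibrium model, so the sampler draws coefficients directly:
log₁₀β_i ~ U(−a, a), then log₁₀α_i ~ U(−a, log₁₀β_i). Exactly zero α_i
(allowed by the constraints but unreachable log-uniformly) is not drawn by
default, matching the printed sampling rule; boundary responses such as
strict fractional saturation are still constructible explicitly.

**Unconstrained coefficient sampler**: α_i drawn independently on the same
box, so α_i > β_i occurs and points can leave the equilibrium region.

**Hypercube label samplers** (fractional-saturation output): nonequilibrium —
every directed edge label log-uniform on [−a, a], generically violating the
cycle condition; the response's rational coefficients are recovered exactly
from the Matrix-Tree polynomials (denominator degree 2^m − 1 on C_m, e.g. 3
for m = 2, strictly above the equilibrium degree m). Equilibrium control —
vertex weights log₁₀γ_S ~ U(−a, a) determine every label ratio, enforcing the
cycle condition by construction.

**Random graph fixtures**: each binding pattern of C_m receives 1–2 vertex
copies (standing in for unnamed molecular features), chained by non-binding
edges and joined across patterns through random copy pairs. Equilibrium
labelings set each label ratio to γ_target/γ_source. These fixtures emulate
the *structure* of real regulatory models (hidden states decorating a binding
hypercube); they do not emulate measurement noise, ligand depletion, or
oligomerization, so passing tests demonstrate the mathematical identities and
barrier dichotomy, not robustness to experimental artifacts. The generic
nonequilibrium fixture for the χ-dependence dichotomy is the fully decorated
hypercube (two copies per pattern, all cross-edges), whose parallel binding
routes make the x-dependence of χ pronounced; sparser random graphs can have
nearly lopsided blocks whose χ variation is small in absolute terms.

Default rate/weight spreads are a = 1 (rates within one decade of 1) for
fixture graphs — typical of the few-decade spreads of biochemical on/off
rates — and a = 3 for region and barrier sampling, wide enough for the region
boundary to stabilize at the scales studied here.

## Region estimation

The (p, s) plane is gridded into square cells of side 0.005. After an
initial batch of raw draws, the *working boundary* — occupied cells with an
empty 4-neighbor — is refined in two alternating phases per boundary cell:
(1) mutate the cell's archived parameter set until a mutant lands in an empty
cell; (2) place a target outside the boundary (3 cell widths outward along
the mean empty-neighbor direction) and keep mutations greedily whenever they
reduce the distance to it, which pulls the search out of valleys phase 1
cannot escape. Mutations multiply each parameter by 10^ε, ε ~ U(−δ, δ) with
δ = 0.25, clipped back to the sampling box (α re-clipped to [10^{−a}, β_i]
after every move, so the equilibrium constraints survive mutation). The run
converges when no new boundary cell has appeared for a set number of
consecutive boundary-cell iterations (default 1,500; desk-scale runs use
200). All randomness flows through one seeded generator, so runs replay
exactly.

Two deliberate design choices:

- **Computation window.** The (p, s) regions have wings asymptotic to both
  axes; in particular steepness is unbounded as p → 0 (points with s ~ 1e10
  arise already for l = 2, a = 3). On an unbounded sparse grid the boundary
  chase would keep discovering new wing cells indefinitely and the stagnation
  criterion could never fire, so the estimator tracks a finite window
  (default p, s ≤ 1.25, covering the Hill cusp region for m ≤ 4; points
  outside are counted, not gridded). The window is the computational
  counterpart of truncating plots to the area of interest; the wings it
  excludes are not the biologically meaningful part of the region.
- **Iteration granularity.** Convergence counts boundary-cell processing
  steps, not whole boundary sweeps: at cell size 0.005 a dense region's
  working boundary holds thousands of cells, and sweep-level stagnation
  would multiply the convergence tail by that factor without changing what
  is explored.

Phase attempt budgets default to 200 per cell; the desk-scale acceptance
runs use 40, which at the two-site scale leaves the estimated boundary
visually and numerically indistinguishable near the cusp while keeping the
three-run (a = 1, 2, 3) comparison a few minutes long.

## Problem sizes used in the shipped checks

The acceptance-grade checks run at reduced scale chosen as this package's
own study conditions: two input binding sites (so the barrier is H₂),
10⁵ equilibrium coefficient draws, 10⁴ hypercube label draws per arm, region
runs seeded with 2×10⁴ draws at stagnation limit 200 within a (0.9, 0.9)
window, and fixture families of 20 random graphs (≤ 12 vertices). The
four-site pipeline is exercised end to end (16-vertex determinants) but its
asymptotic region is not re-estimated.

## Known limitations

- Exact symbolic work (tree enumeration, Fraction determinants) is intended
  for graphs up to tens of vertices; no sparse or structured determinant
  algorithms are provided.
- Nonequilibrium responses are handled numerically per graph; no general
  symbolic characterization of their coefficients is attempted, and nothing
  is claimed about the shape of nonequilibrium (p, s) regions beyond the
  existence of barrier-exceeding points.
- The boundary-search hyperparameters (mutation kernel, attempt budgets,
  target geometry) are declared package choices; the estimator's output is an
  inner approximation of the reachable region and inherits Monte-Carlo
  variability outside the seeded configurations.
- Hill functions with non-integer coefficient go through the numeric
  optimizer; its half-line cap (default y ≤ 1e9, compactified) bounds how
  closely suprema approached only at infinity are resolved.
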