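# hillbarrier

Exact steady-state analysis of ligand-binding Markov models and the
Hill-function barrier for the sharpness of input–output responses.

Biochemical input–output responses — receptor occupancy, gene activation,
enzyme flux — are routinely summarized by a Hill coefficient, yet the Hill
function *H_h(x) = x^h / (1 + x^h)* has no mechanistic basis for *h ≠ 1*.
This package implements the graph-theoretic machinery that gives it one: for
any finite-state, continuous-time Markov model in which an input ligand binds
at *m* sites (first-order binding, reservoir conditions), the Hill function
*H_m* is the sharpest response achievable at thermodynamic equilibrium.
Responses sharper than *H_m* in **both** of the intrinsic sharpness measures
(position and steepness) certify that the underlying mechanism dissipates
energy.

Who it is for: systems-biology and biophysics researchers who model dose
responses with discrete-state (linear-framework) Markov models and want exact
steady states, principled sharpness measures, or an energy-expenditure test
for experimental response curves.

## What it computes

Vertices of a labeled digraph *G* are molecular states, edges are transitions,
and an edge at which the input (concentration *x*) binds carries label
*rate · x*. For strongly connected *G* the steady state follows from the
Matrix-Tree theorem,

    ρ_i(G) = Σ_{T ∈ Φ_i(G)} Π_{u→v ∈ T} ℓ(u→v),      u*_i = ρ_i / Σ_j ρ_j,

where *Φ_i* is the set of spanning trees rooted at *i*. At thermodynamic
equilibrium (detailed balance ⇔ the cycle condition μ(cycle) = 1 on label
ratios) the Boltzmann-like path weights μ_i = γ_i x^{b_i} give the same
distribution, with *b_i* the number of bound input sites.

- **graph_core / steady_state** — graph construction (hypercubes C_m and
  substructures), Laplacian, exact tree enumeration and integer tree counts,
  ρ and μ vectors, cycle-condition and path-entropy diagnostics.
- **coarse_grain** — reduction of any reversible model onto its input-binding
  patterns: coarse labels ℓ(w→z) = Q·Σ_{j∈z} ρ_j make the coarse steady state
  equal the block sums of the fine one, with the conditional probabilities
  χ_i = u*_i / (block sum) x-independent exactly at equilibrium.
- **response** — responses r(x) = Σ λ_i u*_i (0 ≤ λ_i ≤ 1) and their
  universal equilibrium rational form
  r(x) = (α_0 + … + α_l x^l)/(β_0 + … + β_l x^l) with β_i > 0,
  0 ≤ α_i ≤ β_i, and *l* the maximum number of concurrently bound sites.
- **sharpness** — intrinsic normalization x_0.5 and the scale-invariant
  position/steepness pair (p, s), computed by polynomial root isolation.
- **region** — occupancy-grid estimation of (p, s) regions with the two-phase
  mutation boundary search, plus nonequilibrium hypercube samplers that
  escape the Hill barrier.

## Worked example

Two-site binding with strong positive cooperativity (first site weak,
second site 25× stronger; association constants chosen so the cycle
condition holds), output = fractional saturation:

```python
import hillbarrier as hb

rates = {("0","1"): 0.2, ("1","0"): 1.0, ("0","2"): 0.2, ("2","0"): 1.0,
         ("1","1+2"): 5.0, ("1+2","1"): 1.0, ("2","1+2"): 5.0, ("1+2","2"): 1.0}
G = hb.build_hypercube(2, rates=rates)

hb.cycle_condition_satisfied(G)      # True  (an equilibrium model)
hb.steady_state(G, 1.0)              # [0.4167 0.0833 0.4167 0.0833]

w = hb.fractional_saturation_weights(G)   # λ = (0, 1/2, 1/2, 1)
r = hb.equilibrium_rational_form(G, w)
r.alpha, r.beta                      # (0.0, 0.2, 1.0), (1.0, 0.4, 1.0)

sp = hb.position_steepness(r)
(sp.p, sp.s, sp.x_half)              # (0.457, 0.5968, 1.0)
hb.hill_point(2)                     # (0.5774, 0.6495)
```

The response is the rational function r(x) = (0.2x + x²)/(1 + 0.4x + x²):
degree 2 because two input molecules can be bound at once, with every
numerator coefficient dominated by its denominator partner — the signature of
an equilibrium response. Its sharpness point (p, s) = (0.457, 0.597) lies
below and to the left of the Hill point of H₂ at (0.577, 0.650): even this
strongly cooperative equilibrium model cannot beat the Hill function in both
measures. Away from equilibrium it can:

```python
import numpy as np
pts = hb.nonequilibrium_ps_sample(2, 3.0, 500, np.random.default_rng(1))
len(hb.exceeds_hill_barrier(pts, 2))     # 6 of 500 beyond H2 in both p and s
eq = hb.equilibrium_hypercube_ps_sample(2, 3.0, 500, np.random.default_rng(1))
len(hb.exceeds_hill_barrier(eq, 2))      # 0
```

One of the escaping nonequilibrium points is (p, s) = (0.609, 0.657) — beyond
H₂ in both coordinates, which no equilibrium labeling achieves.

A command-line interface mirrors the library
(`hillbarrier graph steady-state`, `hillbarrier region estimate`, …); see
`hillbarrier --help`.

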