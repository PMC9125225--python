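# Methods

## Model and conventions

A composite system is a finite product space X = ∏ᵢ Xᵢ with named
coordinates, evolving under a master equation dp/dt = K(t)p.  All vectors
and matrices use one flat enumeration: lexicographic with the **last listed
coordinate varying fastest** (NumPy C order).  The rate-matrix entry
convention is `K[x, x′] = rate of x′ → x` (column = source), so columns of a
generator sum to zero.  The literature is split on this; every matrix in
the package follows this one convention.  All information quantities are in
nats, k_B = 1, with 0·ln 0 = 0.  Distributions must be normalized to 1e-9
at construction; renormalization requires an explicit flag and never
happens silently.

### Reservoir structure

Each reservoir v carries a puppet set P(v) (coordinates it can move) and a
leader set L(v) ⊇ P(v) (coordinates its rates may read).  A reservoir's
rates are stored compactly as a table `T[a, l]` — destination puppet
configuration × source leader configuration — and embedded into the joint
space as `K[(a, ctx), (l, ctx)] = T[a, l]` for every context of the
untouched coordinates.  Validation checks four invariants at sampled
protocol times (tolerance 1e-10): non-negative off-diagonals, zero column
sums, transitions moving only puppets, and dependence on leaders only.  The
last two can only be violated by full-matrix reservoirs, which exist mainly
so that tests can express invalid couplings.

Time dependence comes in three protocol flavours: constant,
piecewise-constant segments, and arbitrary callables.  Structural
properties (unit membership, multipartiteness, validation) are checked at a
finite time sample: a single time for constant protocols, otherwise segment
boundaries plus ten interior points.  This is exact for constant and
piecewise-constant protocols and a heuristic for callables.

### Units and structures

A unit is a coordinate set ω whose marginal generator exists: summing the
destination states of the outside coordinates must give a matrix
independent of the outside *source* state (tolerance 1e-10); the failure
mode returns the maximal spread and a witnessing transition.  A unit
structure must cover all coordinates and be closed under non-empty
intersection; the full coordinate set is excluded by default (the height-2
bound below is stated for structures without it) and admitted behind
`allow_full=True`.  Validation reports seven flags: coverage, closure,
membership, flush (every simultaneously-changing coordinate set lies inside
some unit), no vacuous units, no equivalent nested units, and tightness
(every reservoir of ν(ω) has its leader set inside ω).  The equivalence
check is structural (full support) by default, with an optional
distribution-aware mode restricted to the support of a supplied p.

The inclusion–exclusion sum Σ̂_ω f_ω runs over **all** 2ⁿ−1 non-empty index
subsets with sign (−1)^{|S|+1}, f evaluated at the subset's intersection;
repeated intersections are counted once per index subset, and empty
intersections contribute f(∅) = 0.  Above 20 units the sum refuses to run.
The in-ex information is I_N∗ = Σ̂ S_ω − S_N; for disjoint families it
reduces to multi-information and for two disjoint units to mutual
information, both verified to 1e-12 by property tests.

## Thermodynamic functionals

EF rates use the Schnakenberg form Σ_{x≠x′} L_{xx′} p_{x′} ln(L_{xx′}/L_{x′x})
summed over the relevant reservoir set (all reservoirs globally, ν(ω) for a
unit; EF is additive over reservoirs, which the code exploits by computing
one EF-rate series per reservoir).  One-way transitions (forward rate
positive, reverse zero) are rejected at evaluation time — the log-ratio
would be undefined — rather than producing infinities; all packaged
generators have symmetric support.  EP rates add the entropy derivative:
the global EP rate equals Σ L p′ ln(Lp′/L̃p) and is non-negative by the
log-sum inequality; it returns +inf when a zero-probability state receives
current (possible at deterministic starts).

Per-unit EP requires the unit's own self-contained generator, which by the
tight-structure property is the sum of the ν(ω) reservoir matrices
restricted to ω; non-tight units are refused, not approximated.
**Integrated** per-unit EP is computed as σ_ω = ΔS_ω + Q_ω from the
endpoint marginal entropies and the quadrature of the EF rate.  This is
definitionally equivalent to integrating the EP rate but avoids its
integrable log-divergence at deterministic initial conditions, where the EF
rate stays finite.

Quadrature uses Simpson's rule on the evolution grid with a trapezoid
cross-check; if the two disagree beyond tolerance (1e-6, loosened
proportionally for large EF) the integration raises and asks for a denser
grid.  Piecewise-constant protocols are propagated exactly by matrix
exponentials per grid step (with propagator caching), so the grid density
only limits the quadrature, not the dynamics; arbitrary protocols fall back
to LSODA at rtol 1e-8.  Joint spaces are warned/refused above ~20,000
states — this is a desk-scale tool.

The integrated report records the in-ex EF decomposition residual
pointwise (an exact identity; observed at machine precision), the EP
decomposition residual |σ_N − (Σ̂σ_ω − ΔI)|, the SSL bound B = −ΔI with a
`guaranteed` flag that is true only for dependency-graph height ≤ 2 (B is
still computed for taller structures, and its sign is whatever it is — it
can be negative), and the inequality checks: σ ≥ 0 globally and per unit,
σ_ω ≥ σ_α for nested units, the disjoint-sum bound, and σ_N ≥ B.

## Feedback control

The controller is one extra coordinate, listed first in the extended space,
pinned by a zero-rate reservoir (so its marginal is conserved exactly) and
readable by the system reservoirs through their leader sets.  The
measurement's own thermodynamic cost is excluded.  Lifting a structure
appends C to every unit; if two original units were disjoint their lifts
intersect in {C} alone, so the bare controller unit is added to restore
closure (it is trivially a unit).  The bound difference
B_M∗ − B_N∗ = Δ[Σ̂ I(X_ω;C)] − ΔI(X_N;C) holds as an identity whenever the
controller marginal is conserved, and is verified to 1e-10.  The work
bounds Δ[Σ̂ S(X_ω|C)] (structure-aware) and ΔS(X_N|C) (conventional) are
information-theoretic statements; their interpretation as extractable work
additionally assumes a uniform endpoint Hamiltonian, one temperature, and
local detailed balance, which the package does not model — both bounds are
reported and their ordering is recorded, not assumed.

## Packaged examples and what they emulate

**Sensing network** (`build_fig1`): four subsystems, singleton puppet sets
(a multipartite process), leader sets 3→{3}, 2→{2,3}, 1→{1,2}, 4→{3,4},
structure {{1,2,3},{3,4},{3}} (two roots, one leaf, height 2).  Rates are
seeded uniform draws in [0.5, 1.5]; the initial distribution is a seeded
Dirichlet(1) draw.  This emulates two cells reading a shared external
signal; it does not model any specific biochemistry.

**Three-subsystem relaxation** (`build_example2`): the endpoint conditional
p(x₁|x₂)p(x₃|x₂)p(x₂) is what the analysis needs, but no concrete protocol
achieves it uniquely; the fixture uses a two-stage piecewise-constant
protocol — stage 1 uniformizes subsystem 2 while 1 and 3 already relax
toward x₂-conditioned jump targets, stage 2 freezes 2 and lets 1 and 3
finish.  Keeping 1 and 3 active in stage 1 avoids a degeneracy in the
equivalent-units check that a "freeze 1 and 3 first" protocol would
create.  Targets q(x|x₂) are seeded draws in [0.15, 0.85] (bounded away
from 0 and 1 so rates keep symmetric support).  The default relaxation time
(30, rate 1) leaves a factorization residual ≈ 1e-8, checked at build time
against a 1e-4 gate.  The SSL bound is ln 2 regardless of the seed.

**Coarse-grained walker** (`build_walker`): positions x₁, x₂ within an
L×L square, square index x₃ on an N×N torus, nutrient stores A (reads x₁)
and B (reads x₂).  The walk fires both directions at rate 1; crossings
step x₁ (or x₂) and x₃ simultaneously (deterministically — the crossing
target square is fixed by geometry), so the process is not multipartite.
Structure {{1},{2},{1,2,3},{A,1},{B,2}}, height 2.  This structure is
**not tight**: the boundary-crossing reservoir has puppet and leader set
{1,3} and also drives the unit {1}.  Tightness is needed only for per-unit
EP, which the walker analysis does not use; the SSL bound needs endpoints
only.  Default runtime is ~40 relaxation times of the slowest position
mode, after which the joint distribution is the product
u(x₃)·π(A,x₁)·π(B,x₂) to ≤1e-6 (the position dynamics is
translation-invariant across squares and the two walk/nutrient pairs never
interact).

**Known discrepancy.**  A quoted value for the walker scenario states that
the information drop −ΔI equals 2 ln L from a deterministic start to the
uniform-position endpoint.  That figure corresponds to truncating the
inclusion–exclusion expansion at second order.  Under the full definition
the two non-empty triple intersections ({1} and {2}, each arising from
{leaf} ∩ {1,2,3} ∩ {nutrient unit}) contribute −S(1)−S(2), which collapses
the in-ex information to S(A,B|1,2,3) − S(A|1) − S(B|2); at product-form
endpoints this is exactly zero, so the strict bound degenerates to the
conventional second law.  The three-subsystem example, whose arithmetic
requires the third-order term, confirms that the full expansion is the
consistent definition, so the package implements it and the walker fixture
records both numbers (`minus_delta_I = 0`,
`minus_delta_I_second_order = 2 ln L`).  The acceptance-suite test that
asserts the quoted 2 ln L value therefore fails by design.

**Random systems** (`random_unit_system`): one reservoir per coordinate
with leader set equal to the smallest unit containing it; this makes any
given structure valid and tight by construction, and is how the Monte-Carlo
suites (100 decomposition runs, 200 inequality runs, on 3–4 binary
coordinates over [0, 2] with 161-point grids) draw their systems.  Passing
these suites shows the identities and inequalities hold across the sampled
rate/structure ensemble; it does not probe large state spaces, stiff rate
separations, or time-dependent driving beyond piecewise-constant scaling.

## Degenerate inputs and tie-breaks

Zero-rate reservoirs are valid (frozen coordinates); a frozen coordinate is
trivially a unit.  Duplicate puppet sets are rejected unless explicitly
allowed.  Units are canonically ordered by size then name tuple, making
reports and search output deterministic.  `enumerate_height2_structures`
does exhaustive subset search over verified units (≤12 coordinates) rather
than any constructive recipe, and flags partial results if the search
budget is exhausted.  `conditional_consistency_check` implements necessary
conditions only (each unit's marginal kernel must ignore outside initial
states); deciding whether a kernel is realizable by a structure-obeying
generator is an embedding-existence problem that the package does not
attempt.
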