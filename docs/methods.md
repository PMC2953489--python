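# Methods

## Model and assumptions

The package models two large, well-mixed populations whose individuals hold
a behavior (1 or 2) and revise it by imitating more successful members of
their *own* population.  Preferences are incompatible: population a prefers
behavior a, and each population's payoff matrices label its own preferred
behavior as "cooperative", so population 2's matrices are the double-flipped
(mirrored) forms of population 1's.  Payoffs enter only through differences,
B = S − P and C = R − T, evaluated separately for in-group encounters
(b_a, c_a) and cross-group encounters (B_a, C_a).  The power f ∈ [0, 1]
weights how much population 1's members determine expected payoffs; it can
stand for relative size, resources or influence, and is deliberately
decoupled from the finite-population sizes in the stochastic model so both
can be varied independently (a convenience constructor couples them when
population size *is* the intended meaning of power).

Proportional imitation in the large-population limit yields the coupled
replicator system

    dp/dt = p(1−p) G₁(p, q),    dq/dt = q(1−q) G₂(p, q),

with affine growth brackets

    G₁ = f[c₁p + b₁(1−p)] + (1−f)[C₁(1−q) + B₁q],
    G₂ = (1−f)[c₂q + b₂(1−q)] + f[C₂(1−p) + B₂p].

The out-group terms use the partner's *actual* behavior: a cross-group
partner of population 1 shows behavior 1 with probability 1 − q.  The unit
square, its edges and corners are invariant.  A useful identity: with
identical in- and out-group parameters ("shorthand" B, C), G₁ + G₂ ≡ B + C
for every f, so an interior rest point exists only when B + C = 0 — in which
case both brackets vanish on the whole line f(1−2p) + (1−f)(2q−1) = 0, a
continuum of equilibria (attracting on the snowdrift branch B > 0, repelling
on the stag-hunt branch B < 0).

Assumptions worth keeping in mind: infinite well-mixed populations (for the
ODE), constant preferences and power, no mutation, no spatial or network
structure, exactly two behaviors and two populations.

## Transformations

*Costly punishment.*  An individual receiving the sucker's payoff punishes
its partner: cost γ_a to the punisher, fine β_a to the punished.  In-group:
b′_a = b_a − γ_a, c′_a = c_a + β_a, so an in-group prisoner's dilemma
becomes a stag hunt exactly when β_a > |c_a|.  Cross-group encounters with
discoordinated behavior are perceived as unilateral cooperation by *both*
sides, so by default both punish: B′_a = B_a − γ_a − β_other, C′_a = C_a
(`cross="both"`).  The one-sided variant B′_a = B_a − γ_a is available as
`cross="one_sided"`; every benchmark outcome in this package holds under
either rule, because both leave the cross-group prisoner's dilemma a
prisoner's dilemma while hardening B.  The benchmark punishment scenario
uses γ = 2.5 and β = 5γ = 12.5; with these values the punished system has
three asymptotically stable corners (0,0), (1,0), (0,1), i.e. punishment can
establish either shared norm — or fail, if the initial cooperation level is
low.  Fines below costs are permitted but warn, as the usual convention is
β ≥ γ.

*Group pressure.*  Subtracting g ≥ 0 from the discoordination payoffs S and
T maps (B, C) → (B − g, C + g); a prisoner's dilemma becomes a stag hunt
exactly when g > |C|.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` (RK45) with rtol = 1e−9,
  atol = 1e−11.  The vector field clamps its input to [0,1]², so round-off
  can never push trajectories outside; recorded states are clamped again
  (tolerance 1e−12).
* Convergence: a terminal event fires when the sup-norm of the vector field
  drops below eps_conv = 1e−9; `find_attractor` escalates time budgets
  (10², 10³, 10⁴) and reports non-convergence rather than rounding to a
  nearby point.  These tolerances resolve attractor coordinates to ~1e−8,
  comfortably inside the 1e−4 agreement the benchmark checks use.
  Convergence onto an equilibrium continuum is detected by the same
  field-norm criterion, never by proximity to a precomputed point list.
* Equilibria: edge and interior rest points come from exact affine solves.
  Coincidence of the two zero-sets (a continuum) is declared when all 2×2
  minors of the sup-norm-normalized augmented system are below 1e−10.
  Stability uses the closed-form Jacobian; eigenvalue real parts within
  1e−8 of zero are reported "nonhyperbolic" and such points are excluded
  from basin labeling.  Edge points are classified with the full 2D
  Jacobian, so transversally repelling edge points correctly appear as
  saddles.  Distinct points closer than 1e−8 are merged.
* Basins and sweeps: attractor labels require the endpoint within
  match_tol = 1e−3 of a named point or the continuum segment; anything else
  (including budget exhaustion) is "unresolved", never nearest-matched.
  Discontinuity detection flags adjacent sweep values whose attractor
  coordinate jumps by more than jump_tol = 0.5.  Phase-diagram sweeps start
  at (1−ε, 1−ε) with ε = 1e−3, because the nominal "everybody shows its
  preferred behavior" start (1, 1) is itself stationary; ε is configurable.
  Default sweep granularity is 101 values per axis, with the cubic path
  C = −B³ over B ∈ [−1.5, 1.5] for the revolutionary-transition sweep.
  Two incidental facts about that cubic path at f = 0.8 matter for test
  design: at B = 1 the start (0.5, 0.5) lies exactly on the equilibrium
  continuum, and at B = 0.5 the edge equilibrium p* = 1/(f(1+B²)) merges
  with the corner (1,1) (a nonhyperbolic point with algebraic convergence),
  so test sweeps sample grids avoiding those exact values.

## Stochastic counterpart

The agent-based chain keeps counts (k₁, k₂) of preferred-behavior adopters.
Each elementary event picks a population with probability proportional to
its size, draws focal and model agents without replacement, and copies the
model's behavior with probability max(0, ΔE)/Δmax, where ΔE is the expected
payoff difference at the current state and Δmax = max |G_a| over the corners
of the square (a single global normalization keeping probabilities in
[0, 1]).  One generation is N₁ + N₂ events; the expected one-generation
change equals the replicator flow over Δt = (1/Δmax)·N/(N−1), which the test
suite verifies against the ODE flow map.  A single seeded generator drives
each run; replicates offset the seed deterministically, and runs are
bitwise reproducible.  States with k ∈ {0, N} in both populations are
absorbing (no mutation by default; an exploration rate would be a
straightforward extension but is deliberately absent to match the
deterministic model).  The inner loop is compiled with numba when available
and falls back to pure Python otherwise.

## Benchmark scenarios (the synthetic inputs)

`popgames.fixtures.generate_fixtures()` encodes the benchmark parameter
sets: prisoner's dilemma and harmony at B = C = ∓1 with f = 0.8; stag hunts
at (|B|, |C|) ∈ {(1,1), (1,2), (2,1)} with f ∈ {1/2, 0.8}; snowdrifts at the
mirrored magnitudes; the punished prisoner's dilemma (B = −1, C = −2,
f = 0.8, γ = 2.5, β = 12.5); and the mixed case of a stag-hunt population
facing a prisoner's-dilemma population at f = 1/2.  These are *parameter*
fixtures, not data: the model has no external data inputs, so the only
idealizations to flag are the model's own (well-mixed infinite populations,
fixed preferences).  Passing tests show the implementation reproduces the
model's attractor structure at these parameters; they say nothing about how
well the model describes any empirical social system.

Problem sizes used by the test suite were chosen to keep a full run at a
few minutes on one core: basin maps at n = 21 (with one 21-vs-101
refinement check), 100 random starts per flow-vs-equilibria consistency
check, a 200×200 grid-scan oracle, 1000 random draws for the Jacobian
oracle, and stochastic runs with N = 2000 per population, 100 replicates
and 100 generations (≈ 100 payoff-normalized e-folding times for the
benchmark sets, an order of magnitude beyond the deterministic convergence
time).  The mean-field ladder check uses N ∈ {100, 1000, 10000} with 20
replicates over 5 generations.

## Known limitations

* Nonhyperbolic rest points are reported but not analysed further (no
  center-manifold reduction or Lyapunov functions); near such points
  convergence is algebraic and the integrator may exhaust its budget,
  which is reported honestly as "unresolved".
* Transitions are located by dense sweeps, not continuation methods, so a
  transition locus is an interval between sweep values.
* The phase-diagram threshold curve (who sets the norm, as a function of f
  and b/c) is computed numerically; no closed form is asserted.
* Interaction rates between populations beyond the single power weight f
  (e.g. a separate cross-encounter rate) are not modeled.
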