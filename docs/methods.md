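# Methods

This document records the mathematical models implemented by `cpepa`, the
assumptions behind them, the numerical choices, and the known limitations.

## 1. Language and structured semantics

A model is a finite set of sequential definitions `Name = body;` plus a
`system` equation.  Sequential bodies are prefixes `(action, rate).Next`,
choices `P + Q`, and references to other definitions.  Rates may be numeric
literals, named rate constants (`r = 24;`), or scaled constants
(`0.2 * r_scan`), the scale being recorded as the branch `weight`.  System
expressions combine replicated components `Name[n]` with cooperation
`L <a, b> R` (synchronisation on the listed actions) and interleaving
`L || R`.

Transitions follow classic PEPA semantics with bounded capacity:

- A non-shared action executes independently in each component that enables
  it (interleaving).
- A shared action executes at the **minimum of the apparent rates** of the
  two sides, where the apparent rate of an action in a component is the sum
  of the rates of all its enabled transitions for that action, and the
  apparent rate of a replicated group is (enabled copies) × (per-copy
  apparent rate).  An individual transition with local rates `r_l`, `r_r`
  inside sides with apparent rates `R_l`, `R_r` fires at
  `(r_l/R_l) · (r_r/R_r) · min(R_l, R_r)`.

Branch probabilities in a choice are expressed as rate scaling: a routing
probability ρ at a department with service rate μ becomes a prefix with rate
ρ·μ (weight ρ), so that the total outflow rate of the department is
conserved at μ.

Validation rejects dangling references, duplicate definitions, non-positive
rates, synchronisation sets containing actions absent from both sides, and
branch-probability sums ≥ 1.

## 2. CTMC derivation and solution

The global state is the tuple of local-state indices of every component
copy; replicated copies of the same definition form a *group* and their
sub-tuple is kept sorted, which quotients away the irrelevant identity of
identical copies during exploration.  Breadth-first exploration with
lexicographically sorted successors makes the state ordering deterministic.
The generator `Q` is assembled sparse (COO → CSR); `πQ = 0, Σπ = 1` is
solved by replacing one balance column with the normalisation row and
calling a sparse direct solver, with a dense least-squares fallback.
Irreducibility is checked via strongly connected components
(`ReducibleChainError` otherwise); the accepted residual is ≤ 1e-10.

## 3. Counting abstraction (aggregation)

States are mapped to *count vectors*: for each group, how many copies are in
each local state.  Under the semantics above this is an exact (strong)
lumping — all states with the same count vector have identical aggregate
outflow to every other class, which the implementation verifies unless
`check_lumpability=False`.  Lumped transition rates are computed from one
representative per class.  Steady-state measures (expected busy counts,
action fluxes) are preserved exactly; the test suite asserts this both on
the worked example and on randomly generated pathways.

For the simple two-patient pathway the 10-state chain lumps to 5 classes;
at 8 patients / 8 waiting rooms / 3 resources the full chain has 75 582
states, which the explorer enumerates in a few seconds.

## 4. Fluid (mean-field) approximation

For populations where even the aggregated chain is too large, the count
vector is treated as continuous.  Each action `a` contributes a flux

    f_a(y) = rate(a) · min over participating groups of A_g(a, y)

where `A_g` is the group's apparent count (sum over local states enabling
`a` of count × normalised rate), and the flux is distributed over the
group's competing transitions proportionally to their rates.  The resulting
ODE system is the standard fluid limit of the bounded-capacity semantics;
its drift at the initial state coincides with the expected CTMC drift (a
property the tests check on random models), and trajectories conserve every
group's total count.

**Right-hand side compilation.**  The generic RHS walks the cooperation
tree; for models in which every shared action synchronises along a single
chain of participant groups (true of all pathway-built models) an
equivalent straight-line Python function is generated and `exec`-compiled.
This is ~16× faster and is validated against the tree-walking reference to
≤ 1e-11 in the tests.

**Steady state.**  The ODEs are stiff (waiting-room couplings use rate
1000/day) and approach saturated fixed points along `min`-kinks, so plain
integration to equilibrium is slow.  The solver integrates in doubling
windows (LSODA, rtol 1e-8 / atol 1e-10) and after each window attempts a
damped least-squares Newton polish of the balance equations (one equation
per group replaced by count conservation), with backtracking line search
and clipping at zero.  A candidate root is accepted only if the balance
residual is < 1e-6 **and** the drift Jacobian has no eigenvalue with real
part > 1e-6 — this rejects spurious unstable or deadlocked fixed points
that the algebraic system also admits.  Every stroke-model configuration
solves in well under a second; results are identical (to solver tolerance)
to long plain integration.

## 5. Stochastic probes and passage times

A passage-time query attaches a two-state probe (`NotFinished`/`Finished`)
to the patient component as a product automaton: each patient local state
is split into `State__NotFinished` / `State__Finished`, the trigger action
moves NotFinished → Finished, and all other behaviour is unchanged, so the
probe never perturbs the dynamics (asserted in the tests).  The CDF of the
passage time is the Finished fraction of the probed population over time.

The scenario driver uses a **single tagged patient**: one patient is placed
at the first department in the NotFinished state, all resources idle, and
the fluid ODEs are integrated forward; the CDF is the tagged patient's
Finished probability.  With one patient the fluid equations are exactly the
Kolmogorov forward equations of that patient's CTMC, so the result is
exact, and it is invariant to the resource multiplicities (an idle system
never queues a lone patient) — the acceptance tests verify the invariance
between the (1, 1, 8) and (3, 3, 20) resource sets.

## 6. The pathway builder and the stroke model

`PathwayConfig` describes departments (name, activity, exponential duration
or rate, optional resource with *held* or *queued* discipline, optional
routing branches), a patient population, and an admission rate.  The
builder emits a cyclic patient chain Home → departments → Home, idle/busy
resource pairs, and numbered waiting rooms for queued resources, and wires
the system equation as a right-nested cooperation whose synchronisation
sets are the pairwise alphabet intersections.

The stroke case study: ambulance FAST test (1 h) holding a stroke team that
is released by the assessment activity; assessment and investigation
(0.75 h); CT scan (3 h) behind a waiting-room queue for the scanners;
hyper-acute treatment (48 h) in a queued bed.  Rates are 24/duration-in-
hours per day: 24, 32, 8, 0.5.  Routing percentages are estimated from
annual activity counts: mimics leaving after assessment
27/(116+15+27) ≈ 17 %, TIA patients leaving after the scan
15/(116+27) ≈ 10 % (whole-percent rounding).  1000 potential patients with
individual stroke rate 0.004/day give 4 patients/day of demand.

**Solver selection.**  Scenario drivers solve the exact aggregated CTMC
when the full-state-space upper bound Π |local states|^copies is at most
200 000, otherwise the fluid approximation; the choice is logged.

## 7. Reference values not reproduced

Two published reference values are inconsistent with the converged model;
the acceptance tests keep the stated tolerances and fail honestly.

1. **Optimal-set bed utilisation (reference 0.92).**  At the optimal set
   (1 team, 1 scanner, 8 beds) the converged fluid steady state gives bed
   utilisation 0.9913.  Flow balance forces this: throughput 3.9651/day ×
   mean treatment 2 days = 7.930 expected busy beds out of 8.  A utilisation
   of 0.92 with 8 beds would imply a throughput of only 3.68/day.  All
   reference utilisations are a uniform ≈ 7–8 % below flow balance, which is
   consistent with a finite-window time-average that includes the empty-system
   warm-up transient rather than the equilibrium value.  (The initial-set
   utilisation, 0.3965 at 20 beds, does match its reference 0.368 within
   tolerance.)
2. **Passage-time CDF (reference 90 % at 2.5 days, 14 % at 1 day).**  Any
   admission-to-discharge passage includes the exponential 48-hour treatment
   stage, so CDF(2.5 days) ≤ 1 − e^(−2.5/2) ≈ 0.713 regardless of the other
   stages or resources; 0.90 at 2.5 days is unattainable for this model
   class.  The probe gives 68.3 % at 2.5 days and 32.8 % at 1 day, and these
   values are resource-set invariant as expected for a lone tagged patient.

## 8. Other limitations

- All durations are exponential; no phase-type or deterministic stages.
- The counting abstraction requires replicated copies to be *identical*
  components; heterogeneous patient classes must be modelled as separate
  groups.
- The fluid approximation is a law-of-large-numbers limit: it is accurate
  for large populations (the tests check a ×100-scaled pathway against the
  exact CTMC within 10 %) and exact for the single-tagged-patient passage
  construction, but can be biased for small, congested populations.
- The compiled RHS fast path covers models whose shared actions synchronise
  along a single participant chain; other topologies fall back to the
  (slower) reference evaluator automatically.
- State-space exploration is bounded (default 2 000 000 states) and raises
  `StateSpaceError` beyond the budget rather than thrashing.
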