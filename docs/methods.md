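# Methods

This note records the model as implemented, the parameters that
matter, the numerical choices, and what the simulations do and do not
establish.

## The vessel-tape machine

The machine operates on an ordered sequence of vessels with a single
head.  The tape is conceptually infinite: moving past either end
materializes a fresh empty vessel (ids `v0`, `v1`, … in creation
order).  Two distinguished vessels live off-tape: **waste**, a
write-only sink whose per-species totals are monotonically
non-decreasing over a run, and **hold**, a recoverable buffer
(condenser/cold-trap stand-in) that lets operations such as
distillation park a fraction and collect it later without violating
waste monotonicity.  Reservoirs are per-species stocks (finite or
unbounded); cumulative drawdown is tracked so the ledger can close.

Amounts are dimensionless mass units.  Reaction rules are mass-typed:
the reactant and product coefficient sums must be equal (checked at
load, tolerance 1e-9), and a product inherits the summed mass of its
reactants.  No molar masses or structures are modeled; species are
opaque labels.  Energy is a per-vessel scalar and is deliberately not
conserved globally — only mass balance is asserted by the model.
AE/SE are clipped at configurable energy limits (default unbounded).

### Symbolization

The underlying formalism leaves open how vessel contents map to a
tape symbol.  The package's contract: an empty vessel reads as the
blank `b`; otherwise the symbol is `(dominant species, condition)`
where the dominant species is the argmax by amount (ties broken
lexicographically, restricted to the reagent alphabet — a vessel
holding only alien species is a symbolization error), and the
condition label comes from ascending energy bands, by default

| label   | energy range        |
|---------|---------------------|
| cold    | e ≤ −0.5            |
| ambient | −0.5 < e ≤ 0.5      |
| hot     | e > 0.5             |

The symbol written after a transition is always re-derived from the
actual vessel contents; a rule's declared `write` is advisory and a
mismatch is recorded as a warning, not an error.

Because a macro-compiled program cannot predict the symbolized
contents in advance, rule reads may use the wildcard `*`, which
matches any symbol at lower precedence than an exact match.  At most
one rule per (state, read) pair is allowed, wildcard included, so the
transition function remains deterministic.

### Step semantics and numerical choices

One step: read, find the unique rule (no rule → `q_fail` with a
diagnostic record), execute the rule's primitive sequence in order on
the head vessel, fire reaction rules, re-symbolize, move, enter the
next state.  Reaction rules fire at most once per step each, in
declaration order (a determinism tie-break); a rule fires when all
reactants are present at their stoichiometric amounts and the vessel
energy lies in the rule's window, converting
`yield_fraction × limiting extent`.

A subtract-matter request larger than what is present is clipped to
the available amount with a warning record — a pump cannot withdraw
absent material, and `q_fail` is reserved for rule-match failure.
The same clipping applies to adds from a finite reservoir.  Amounts
below a pruning epsilon (default 1e-12, configurable) are removed
outright; this bounds the per-record ledger error at well below
1e-12 in practice (measured ~4e-15 over thousands of random runs).

The trace stores, per record, the per-species totals split into tape
/ waste / hold / reservoir drawdown plus cumulative reaction
conversions (`reacted_in` / `reacted_out`).  The conserved net per
species is `tape + waste + hold + reacted_out − drawdown −
reacted_in`; tracking conversions explicitly is what lets the
*per-species* ledger close exactly across transformations rather
than only the total mass.

Runs halt in `q_out` / `q_uout` / `q_nout` / `q_fail` or, distinctly,
`budget_exceeded` when the step budget runs out — an artifact-level
outcome so that non-terminating programs are still total.

## Unit operations and compilation

The canonical macro registry (shipped as YAML) fixes the primitive
sequences of the seven named operations; all amounts, species, and
energy deltas are parameter slots that must be bound at invocation —
no defaults, since process conditions are program data.  Distillation
and sublimation route their removed fraction through the hold vessel
and carry a head move on the cooling primitive, so the final collect
lands in the vessel to the right of the working vessel (the reading
of "collect" adopted here; documented rather than guessed as
authorial intent).  Sublimation's leading SM subtracts a designated
atmosphere species to waste (evacuation) to keep the ledger honest.

`compile_pathway` emits one state per primitive boundary, one
transition per primitive reading `*`, and a terminal transition to
`q_out`; compiled primitive streams are compositional under pathway
concatenation.  Unit-operation boundaries are retained as checkpoint
markers for the error-correction loop.

## Chempiling

The capability map is a direct reading of the module roles: flasks
source AM (routes must cross at least one pump or valve), the
stirrer/heater/cooler realizes AE/SE, separator and chromatography
realize SM (with waste/product vessels as route sinks), sensors are
information-only and scheduling-neutral.  Routing is shortest-path
over the undirected matter subgraph with lexicographic tie-breaks,
so schedules are reproducible.  The chempiler maps onto a *given*
inventory only; synthesizing new graphs is out of scope.  Validation
(required modules, matter connectivity, orphaned nodes) is a separate
report-producing pass and is deliberately not a precondition of
scheduling, which keeps feasibility monotone under adding hardware.

## Error correction

The simulated loop treats the compiled program as ground truth: a
noise-free reference execution provides the expected head-vessel
state at each unit-operation boundary, and the monitored run observes
the true state under multiplicative Gaussian noise (`obs = true ×
(1 + N(0, σ))` per species, seeded) — the checkpoint abstraction
stands in for spectroscopic/chromatographic feedback; no instrument
is modeled.  Deviation magnitude is the maximum relative per-species
error, with unexpected species contributing their fraction of total
expected mass.

Defaults (package calibration choices, configurable, not literature
values): validation tolerance 0.02; severity bands minor < 0.05 ≤
intermediate < 0.20 ≤ major; an unexpected species at ≥ 10 % of
expected product mass forces major.  Actions: minor → parameter
nudge (re-measure), intermediate → repeat/extend (snapshot restore
and deterministic re-execution), major → rollback to the last
validated snapshot.  Each checkpoint spends at most `retry_budget`
interventions before the run is abandoned as `q_fail`.  Because noise
is observational and the machine deterministic, corrections move
matter only through snapshot restores and logged top-ups, so the mass
ledger of a corrected run still closes; with σ = 0 the loop is an
exact fixed point of the plain run.

What a green DEC test establishes: the control logic (classification,
budgets, reproducibility, conservation under intervention).  What it
does not: anything about real sensors, real process noise (which
perturbs the chemistry, not just the measurement), or yield
optimization.

## Halting semantics and the rule database

The database keys on (reagent multiset, condition label, product
multiset), rounded to 9 decimals.  First observation of an unknown
transformation → `q_nout` (recorded as novel); first observation of a
seeded prediction → `q_uout`; either is promoted to characterized so
that the second identical execution halts `q_out`.  Promotion is
identity-based — matching product identity suffices; yields are not
compared (an open reading, resolved toward the weaker requirement).
Statuses never move away from characterized.  A product whose
flawless-copy count fails the detectability test is `q_fail` and is
not committed to the database.

## Assembly calculus

`N_min = φ / Π(1 − ε_k)`.  The division (rather than a product-form
reading) is forced by monotonicity: the copies required for detection
must grow, not shrink, with error and depth.  φ defaults to 10⁶
(typical detection thresholds span 10⁶–10⁸) and is configurable.
Bounds use integer arithmetic (`(B−1).bit_length()`) to avoid
floating log edge cases at powers of two.

The Monte-Carlo uses ε_i = clip(ε₀·e^{k·i} + E_i, 0, 1 − 10⁻⁹) with
E_i ~ N(0, σ) resampled per step per trajectory — the simplest
exponential error-growth law consistent with a stated growth constant,
with the systematic term applied additively.  Trajectories randomize
the error sequence, not molecules: with N₀ ≈ 6 × 10²³ a per-molecule
simulation is impossible and the within-trajectory copy number is the
continuous expectation N_i = N_{i−1}(1 − ε_i).  Seeding: one root
`SeedSequence` spawns a child stream per ε₀; the systematic block is
drawn once per stream, making the table bit-reproducible.  Defaults
are the stated world: N₀ = 6.022 × 10²³, 120 steps, ten baseline
errors 0.01–0.50, k = 0.02, σ = 0.005, 5,000 trajectories.  In the
σ = 0, k = 0 limit the mean reduces to N₀(1 − ε₀)^i exactly (up to
~100 ulp of cumulative rounding, far below the 1e-12 relative
tolerance asserted).  The table reports N_i for i ≥ 1, i.e. the
population *after* each step.

The general assembly index is a hard search problem and is not
implemented; the package provides the theoretical bounds plus an
exact brute-force oracle for tiny graphs: primitives are single
bonds, a step joins two available structures along edge-disjoint
embeddings, built structures are reusable (identified up to
isomorphism), and intermediates are restricted to connected subgraphs
of the target.  That restriction preserves both bounds — each join at
most doubles the edge count, and bond-by-bond growth always succeeds
— so the oracle is valid for bound-checking (exhaustively verified
over every connected graph with at most six bonds), while its
absolute values for graphs whose optimal pathways leave the subgraph
lattice are upper bounds.

## Route dialect and scaling fixtures

The route dialect is a deliberate stand-in, not a reproduction of any
deposited procedure format; the verb → category table (add/transfer →
AM, filter/separate/evaporate → SM, heat/stir → AE, cool/crystallize
→ SE, registered unit ops → composite) is user-overridable.  Step
counts for specific named syntheses depend on deposited files and are
out of scope.

The fixture generator emulates a corpus of executed routes at the
scale of the analyzed dataset: 117 routes, one to three reaction
steps (the strata of the original analysis), six operations per
reaction step drawn i.i.d. from a fixed categorical mix of additions,
conditioning, work-up, and composite operations.  Because the mix is
fixed, the expected expanded count per reaction step is constant, so
the mean cumulative curve is linear by construction — the scaling
test verifies internal consistency of classification + aggregation
(R² > 0.99 on the mean curve), not an empirical fact about laboratory
chemistry.  The per-route totals table is also reported for
distributional views.

## Known limitations

- Species are labels; no structures, no reaction prediction, no
  thermodynamics.  Stability of targets is assumed, not verified.
- The transition function is strictly deterministic; exploratory
  nondeterminism is represented only by the error-correction loop's
  interventions.
- Hardware scheduling ignores timing, volumes, flow rates, and
  dead volume.
- Process conditions live in per-vessel energy bands; pressure,
  atmosphere, and catalysts are not modeled separately (a catalyst is
  just a species that appears on both sides of a reaction rule).
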