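# Methods

This note documents the models implemented in fluxforge, the numerical
choices behind them, and what the test fixtures do and do not demonstrate.

## Model representation

A model is a set of metabolites (internal or external), reactions with
signed stoichiometry and flux bounds, an optional biomass reaction, and
optional GPR rules. Design choices:

* **Reversibility is the bounds.** A reaction is reversible iff its lower
  bound is negative. There is no separate flag that could drift out of sync
  with the bounds.
* **Knockouts close bounds to (0, 0)** instead of deleting the reaction, so
  wild-type and mutant flux vectors share one coordinate system — MOMA and
  ROOM distances require this alignment.
* **External metabolites are excluded from the balance rows** of
  `S·v = 0`. Drains (exchange reactions) touch exactly one internal
  metabolite; a one-sided drain `A →` is normalized at construction to
  carry an explicit external counterpart `A_ext`, so a net conversion is
  always the plain product of the external stoichiometry rows with the flux
  vector.
* **GPR evaluation is pure boolean.** OR means any isozyme suffices, AND
  means every subunit is required; enzyme dosage is out of scope because
  deletions are modelled as on/off events.
* **Infinite bounds are clipped to ±10 000** (flux units) at load: the MILP
  reductions need finite big-M data. The clip value is configurable in
  `fluxforge.config`.
* Structural model equality (used by the round-trip tests) covers ids,
  external flags, stoichiometry, bounds, GPRs and the biomass designation;
  names and compartment labels are display annotations and excluded
  (formats that require a compartment insert a default one).
* Zero tolerance for "a flux is zero" is 1e−6 in flux units throughout.

## Phenotype simulation

**FBA** solves `max/min cᵀv` s.t. `S·v = 0`, `lb ≤ v ≤ ub` with HiGHS.
Shadow prices are the duals of the balance rows, signed so that a positive
value means one extra unit of external supply of that metabolite would
raise the objective (verified in tests by explicit re-solving).

**MOMA** minimizes the squared Euclidean distance to a wild-type reference
distribution over the mutant cone. It is solved as a convex QP with OSQP at
`eps = 1e−10` with solution polishing, which recovers the exact KKT point
on the non-degenerate instances we target (the analytic fixture optimum is
reproduced to 1e−6). The reference defaults to the FBA wild-type solution
under the same environmental conditions; because FBA optima can be
degenerate, the reference used is stored with the result and tests pin
explicit references.

**ROOM** minimizes the number of fluxes leaving the tolerance band
`[w − δ|w| − ε, w + δ|w| + ε]`, with defaults δ = 0.03, ε = 0.001 from the
method's original publication. The MILP uses per-reaction big-M constants
derived from each reaction's own bounds (never a global constant), and the
LP relaxation (`relaxed=True`) relaxes the binaries to [0, 1]; its
objective lower-bounds the MILP's change count.

Either method reports the biomass flux of its minimizer as
`objective_value` and its own criterion (squared distance, change count) in
`metrics` — both are of interest and neither is discarded.

## Variability and MFA

The trade-off tool pins biomass by *equality* at each of n evenly spaced
grid values in [0, wild-type optimum] (endpoints included) and maximizes
the target — "fixed values of the biomass flux" taken literally. Grid
points that fail numerically are flagged, not dropped. Tight bounds solve
2n LPs under an optional biomass floor and measured-flux equalities.

MFA splits `S·v = 0` into measured and unknown columns. Classification:
more independent balance equations than unknowns ⇒ overdetermined; zero
degrees of freedom ⇒ determined; otherwise underdetermined. Determined
systems are solved exactly; overdetermined ones by least squares via the
pseudo-inverse, reporting the residual norm `‖S_u·v_u + S_m·v_m‖` as the
consistency measure. When standard deviations accompany the measurements
they only weight the overdetermined least squares (each balance row by the
inverse of the measurement variance it inherits); no error model beyond
that is assumed. Underdetermined systems fall back to FBA with the
measurements fixed as equality bounds. Rank uses numpy's SVD threshold
(`max_dim · eps · σ_max`). Gross-error and redundancy statistics are out of
scope.

## Simplification

Structural analysis computes the exact rational nullspace of `S` (sympy).
A reaction is structurally blocked iff its nullspace row is zero; two
reactions are equivalent (an enzyme subset) iff their nullspace rows are
proportional, in which case the signed rational flux ratio is recorded.
"Equivalent" is deliberately the proportional generalization of
equal-flux — replacement by a single reaction only needs a fixed ratio.
Sign-incompatible proportional pairs (possible with irreversible members)
are still reported with their signed ratios; the caller decides. Exactness
matters here: proportionality tests on floating-point nullspaces would need
arbitrary thresholds.

FVA-based reduction replaces every reaction's bounds with its computed
envelope and flags (0, 0) reactions as removed; it is valid only under the
environmental conditions used, unlike the structural results.

Essentiality screens single deletions by FBA (the permissive criterion — a
deletion essential under FBA is essential under the more conservative MOMA/
ROOM too) and calls a mutant non-viable below 5% of wild-type biomass; the
threshold is configurable.

## Elementary flux modes

Enumeration splits reversible reactions into forward/backward halves and
iterates the double-description step over the balance rows in exact
rational arithmetic: rays of the current cone are combined pairwise to
annihilate one balance at a time, supports that strictly contain another
surviving support are pruned, and every candidate passes the rank test
`rank(S[:, support]) = |support| − 1` before being reported. Futile
two-cycles (both halves of one split reaction) are discarded. Coefficients
are scaled by the LCM of denominators and divided by their GCD, so modes
are coprime integer vectors with exactly zero steady-state residual.
Fully reversible modes are canonicalized so their first reaction (in model
order) runs forward; modes are returned in lexicographic support order.

Net conversions multiply each mode through the external stoichiometry,
integer-normalize by the GCD, and merge identical balances while recording
the contributing mode indices. Filtering keeps conversions containing all
required and none of the excluded external species; yield sorting orders by
output/input coefficient ratio, placing conversions lacking either species
(including a zero input coefficient) last with yield 0 rather than
guessing an intent for a division by zero.

The enumeration limit defaults to 64 reactions — the double-description
ray count can grow combinatorially, and the intended workflow is to apply
`reduce_model` first. Correctness is established against an independent
brute-force oracle (exhaustive support enumeration with rational
nullspaces) on every network with ≤ 8 reactions in the test suite.

## Strain optimization

Objectives: BPCY = `product · biomass / |substrate|`; Yield =
`product / |substrate|` with score 0 below a minimum-biomass fraction.
Degenerate inputs (zero substrate flux, failed simulation) score 0 rather
than raising, since search procedures must be able to traverse them.

The EA uses a set-based genome (a knockout set), uniform set crossover,
replace/add/remove mutation (add/remove only in the variable-size
representation), tournament selection of size 2, elitism 1, population 100
by default, crossover rate 0.7 and per-element mutation rate 0.1. SA uses a
single replace/add/remove neighbourhood with geometric cooling (factor
0.97) from an initial temperature chosen so the median early uphill move is
accepted with probability ~0.5. These defaults follow the OptGene lineage
of knockout metaheuristics and are all exposed in `MetaheuristicConfig`.
The evaluation budget counts every candidate evaluation, including
memoized re-visits — budgets measure search effort, and caching is an
internal speed-up that must not affect termination. Runs are exactly
reproducible from the seed. Essential reactions/genes are excluded from
the target pool, as are the fluxes defining the objective.

OptKnock is the optimistic bilevel formulation reduced to one MILP: inner
primal feasibility with knockout-gated bounds (`lb·y ≤ v ≤ ub·y`), inner
dual feasibility, and the strong-duality equality, with the bilinear
dual-times-binary terms linearized by McCormick envelopes under a
configurable dual bound (default 1000). A minimum-biomass floor (default
5% of wild type, matching the viability threshold; settable to 0) excludes
zero-growth designs. Because the dual bound and MILP tolerances can in
principle bite, every solution is verified by re-simulation — inner FBA for
the biomass, then product maximization over the inner optimum's alternate
optima — and a disagreement raises an explicit numerical-instability error
instead of returning a wrong design. The pessimistic variant (product
minimized over inner alternate optima) is out of scope.

## Fixtures and what the tests show

The five toy networks are chosen so that every pipeline has a hand-derivable
answer (single chains, parallel routes, dead ends, growth-coupled
production). The random generator builds sparse networks from a guaranteed
uptake-to-biomass backbone plus random small-integer conversions
(coefficients in {−2, −1, 1, 2}, a seeded fraction reversible, extra drains
on random metabolites); small integer coefficients keep exact EFM
arithmetic fast. Test problem sizes — 25 networks of ≤ 12 reactions for the
LP cross-checks and ≤ 8 reactions for the brute-force EFM oracle — are the
scale at which exhaustive oracles are themselves trustworthy.

These fixtures exercise the mathematics, not the biology: they do not
reproduce genome-scale degeneracy (massively alternate FBA optima),
compartmentalized transport, or realistic GPR complexity. Passing tests
demonstrate algorithmic correctness at oracle-checkable scale; behaviour on
genome-scale models additionally depends on LP/MILP solver robustness, for
which OptKnock's verification step and FBA's explicit status reporting are
the guard rails.

## Known limitations

* Kinetic/dynamic models, thermodynamic constraints and regulatory (Boolean
  network) integration are out of scope.
* Metatool files carry no numeric bounds, GPRs or biomass designation;
  conversions through that format are structure-preserving only.
* The flat-file genes list is reconstructed from the GPR rules; genes never
  referenced by any rule do not survive a flat round-trip.
* EFM enumeration is not intended for genome-scale networks.
* MFA offers least-squares reconciliation only — no χ² consistency testing
  or gross-error detection.
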