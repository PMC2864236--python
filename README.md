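# fluxforge

Constraint-based metabolic modelling and *in silico* strain design as a
scriptable Python library and CLI, for metabolic engineers and systems
biologists who want to go from a stoichiometric model to knockout designs
without a GUI workbench.

Given a stoichiometric model — metabolites, reactions with flux bounds, an
optional biomass reaction and gene–protein–reaction (GPR) rules — fluxforge
covers the classic workbench loop:

* **Model handling** — read/write SBML (Level 3 + fbc; Level 2 accepted),
  Metatool text and flat TSV bundles; auto-detect external metabolites and
  biomass candidates from compartments and naming patterns.
* **Phenotype simulation** — FBA, MOMA and ROOM (MILP and LP-relaxed), under
  environmental conditions (drain-bound overrides) and reaction/gene
  knockouts, with net conversions and shadow prices.
* **Flux variability & metabolic flux analysis** — production-vs-growth
  trade-off curves, tight flux bounds under a minimum-biomass floor, and MFA
  with measured fluxes (determined / overdetermined / underdetermined).
* **Model simplification** — structurally blocked reactions and enzyme
  subsets from the exact rational nullspace, FVA-based reduction, and
  essential reaction/gene screening.
* **Elementary flux modes** — complete enumeration in exact rational
  arithmetic, GCD-normalized net conversions, presence/absence filtering and
  yield sorting.
* **Strain optimization** — OptKnock (bilevel MILP via LP duality) and
  set-based evolutionary / simulated-annealing search with Yield and BPCY
  objectives.

## The models in brief

All methods work on the steady-state flux cone
`{v : S·v = 0, lb ≤ v ≤ ub}` where `S` is the stoichiometric matrix over
*internal* metabolites.

| Method | Problem solved |
|---|---|
| FBA | `max cᵀv` (usually biomass) over the cone — LP |
| MOMA | `min Σⱼ (vⱼ − wⱼ)²` over the mutant cone, `w` = wild-type reference — QP |
| ROOM | `min Σⱼ yⱼ`, `yⱼ = 1` iff `vⱼ` leaves `[wⱼ − δ\|wⱼ\| − ε, wⱼ + δ\|wⱼ\| + ε]` — MILP |
| FVA | per-reaction `min/max vⱼ` under a biomass floor — 2n LPs |
| MFA | solve `S_u·v_u = −S_m·v_m` given measured fluxes `v_m` (exact / least squares / FBA) |
| EFM | support-minimal, sign-feasible generators of the flux cone — exact arithmetic |
| OptKnock | `max v_product` over knockout vectors s.t. `v` is inner-FBA-optimal — MILP by strong duality |
| BPCY | `v_product · v_biomass / \|v_substrate\|` — growth-coupled design score |

LP/MILP solving uses SciPy's HiGHS interface, the MOMA quadratic program is
solved with OSQP, and EFM/nullspace analyses run in exact rational
arithmetic (`fractions` + sympy), so steady-state residuals of reported
modes are exactly zero.

## Worked example

The built-in `TOY-COUPLE` network couples growth to by-product secretion:
the uptake `R1: A_ext → A` (max 10) feeds either `R2: A → B` or the coupled
route `R3: 2A → B + P`, with `R4: B → BIOM_ext` as biomass and
`R5: P → P_ext` as the product drain.

```sh
fluxforge fixtures --name TOY-COUPLE --out toy-couple
fluxforge simulate --model toy-couple --method fba --net-conversion-out nc.tsv
```

```
reaction	flux
R1	10
R2	10
R3	0
R4	10
R5	-0
#objective	10
#status	optimal
```

The wild type grows at 10 and secretes no product (`R5 = 0`): the uncoupled
route `R2` is stoichiometrically cheaper. The net conversion (`nc.tsv`)
reads `A_ext −10, BIOM_ext +10`. Now ask OptKnock for one deletion that
forces secretion:

```sh
fluxforge optimize --model toy-couple --method optknock --product R5 --max-ko 1
```

```
deletions	score	biomass	product
R2	5	5	5
```

Deleting `R2` forces all flux through the coupled route: biomass drops from
10 to 5, but 5 units of P are now exported per unit time — the
growth-coupled design. Elementary-mode analysis shows why this is the only
option:

```sh
fluxforge efm --model toy-couple --yield A_ext,P_ext
```

```
conversion	yield	modes
2 A_ext -> BIOM_ext + P_ext	0.5	1
A_ext -> BIOM_ext	0	0
```

The network has exactly two elementary modes; the only product-forming one
converts `2 A_ext → BIOM_ext + P_ext` with a molar product yield of 0.5.
The same analyses are available as library calls (`fluxforge.simulation.fba`,
`fluxforge.optimization.optknock`, `fluxforge.efm.compute_efms`, ...) on any
SBML/Metatool/flat model.

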