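"""Strain optimization: objective functions, EA/SA metaheuristics, OptKnock.

The design problem: choose a set of reaction (or gene) deletions so that the
mutant, while still growing (the cell's own objective remains biomass
maximization), is forced to secrete a product of interest.

Two objective functions are available for the metaheuristics:

* BPCY (biomass-product coupled yield) = product * biomass / |substrate|,
  rewarding mutants whose growth drags product secretion along;
* YIELD = product / |substrate|, subject to a minimum-biomass floor (score 0
  below it).

The evolutionary algorithm and simulated annealing search over knockout
sets directly (set-based genomes, fixed- or variable-size), evaluating each
candidate by phenotype simulation.  OptKnock instead solves the bilevel
program exactly: maximize product flux over binary knockout choices subject
to the inner FBA (biomass maximization) being at its optimum, reduced to a
single-level MILP via LP strong duality.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint

from . import config
from ._solvers import solve_milp
from .model import (
    EnvironmentalConditions,
    MetabolicModel,
    ModelError,
    SimulationResult,
    genes_to_reactions,
)
from .simplification import EssentialitySet
from .simulation import ReferenceFluxes, fba, moma, room, wild_type_reference
from .variability import _lp_extreme
from .simulation import _prepare


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which fluxes define the design objective.

    ``substrate`` is the uptake drain (its flux is consumed, so the absolute
    value enters the denominator).  ``min_biomass_fraction`` only applies to
    the YIELD objective.
    """

    kind: str  # "BPCY" | "YIELD"
    product: str
    substrate: str
    biomass: Optional[str] = None
    min_biomass_fraction: float = 0.1

    def __post_init__(self):
        if self.kind not in ("BPCY", "YIELD"):
            raise ValueError(f"objective kind must be BPCY or YIELD, got {self.kind!r}")
        if not 0 <= self.min_biomass_fraction <= 1:
            raise ValueError("min_biomass_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MetaheuristicConfig:
    strategy: str = "EA"  # "EA" | "SA"
    representation: str = "variable"  # "fixed" | "variable"
    max_knockouts: int = 1
    population_size: int = 20
    evaluation_budget: int = 200
    seed: int = 0
    simulation_method: str = "FBA"  # "FBA" | "MOMA" | "ROOM"
    target_level: str = "reaction"  # "reaction" | "gene"
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    elitism: int = 1
    tournament_size: int = 2
    cooling_factor: float = 0.97

    def __post_init__(self):
        if self.max_knockouts < 1:
            raise ValueError("max_knockouts must be >= 1")
        if self.strategy not in ("EA", "SA"):
            raise ValueError("strategy must be EA or SA")
        if self.strategy == "EA" and self.evaluation_budget < self.population_size:
            raise ValueError("evaluation budget must cover at least one population")


@dataclass(frozen=True)
class KnockoutSolution:
    """A deletion set with its score and the simulation that produced it."""

    deletions: frozenset
    score: float
    biomass_flux: float
    product_flux: float
    simulation: Optional[SimulationResult] = field(compare=False, default=None)


def evaluate_objective(
    spec: ObjectiveSpec,
    sim: SimulationResult,
    wild_type_biomass: Optional[float] = None,
) -> float:
    """Score one simulation under the objective; degenerate inputs score 0."""
    if not sim.ok:
        return 0.0
    product = sim.fluxes.get(spec.product, 0.0)
    substrate = abs(sim.fluxes.get(spec.substrate, 0.0))
    biomass = sim.fluxes.get(spec.biomass, 0.0) if spec.biomass else 0.0
    if substrate <= config.ZERO_TOL:
        return 0.0
    if spec.kind == "BPCY":
        return product * biomass / substrate
    floor = spec.min_biomass_fraction * (wild_type_biomass or 0.0)
    if spec.biomass and biomass < floor:
        return 0.0
    return product / substrate


class _Evaluator:
    """Simulate-and-score with memoization over deletion sets."""

    def __init__(
        self,
        model: MetabolicModel,
        spec: ObjectiveSpec,
        cfg: MetaheuristicConfig,
        env: Optional[EnvironmentalConditions],
    ):
        self.model = model
        self.spec = spec
        self.cfg = cfg
        self.env = env
        self.cache: Dict[frozenset, KnockoutSolution] = {}
        self.evaluations = 0
        wt = fba(model, env=env, with_shadow_prices=False)
        self.wt_biomass = wt.objective_value if wt.ok else 0.0
        self.reference: Optional[ReferenceFluxes] = None
        if cfg.simulation_method in ("MOMA", "ROOM"):
            self.reference = wild_type_reference(model, env)

    def _simulate(self, kos: Set[str]) -> SimulationResult:
        if self.cfg.simulation_method == "MOMA":
            return moma(self.model, self.reference, kos, env=self.env)
        if self.cfg.simulation_method == "ROOM":
            return room(self.model, self.reference, kos, env=self.env)
        return fba(self.model, env=self.env, knockouts=kos, with_shadow_prices=False)

    def __call__(self, deletions: frozenset) -> KnockoutSolution:
        # cached lookups still count against the evaluation budget: the
        # budget measures search effort, and memoization is an internal
        # speed-up that must not change termination behaviour
        self.evaluations += 1
        if deletions in self.cache:
            return self.cache[deletions]
        if self.cfg.target_level == "gene":
            kos = genes_to_reactions(self.model, set(deletions))
        else:
            kos = set(deletions)
        sim = self._simulate(kos)
        score = evaluate_objective(self.spec, sim, self.wt_biomass)
        sol = KnockoutSolution(
            deletions=deletions,
            score=score,
            biomass_flux=sim.fluxes.get(self.spec.biomass, 0.0) if sim.ok and self.spec.biomass else 0.0,
            product_flux=sim.fluxes.get(self.spec.product, 0.0) if sim.ok else 0.0,
            simulation=sim,
        )
        self.cache[deletions] = sol
        return sol


def _candidates(
    model: MetabolicModel,
    spec: ObjectiveSpec,
    level: str,
    excluded: Optional[EssentialitySet],
) -> List[str]:
    if excluded is not None and excluded.level != level:
        raise ModelError(
            f"exclusion set is {excluded.level}-level but optimization targets {level}s"
        )
    drop = set(excluded.essential) if excluded is not None else set()
    if level == "gene":
        if not model.genes:
            raise ModelError("gene-level optimization needs gene-reaction rules")
        pool = sorted(model.genes)
    else:
        pool = model.reaction_ids
        # never target the fluxes that define the objective itself
        drop |= {spec.product, spec.substrate}
        if spec.biomass:
            drop |= {spec.biomass}
        if model.biomass_reaction:
            drop |= {model.biomass_reaction}
    out = [c for c in pool if c not in drop]
    if not out:
        raise ModelError("no knockout candidates remain after exclusions")
    return out


def _random_set(rng: random.Random, pool: Sequence[str], cfg: MetaheuristicConfig) -> frozenset:
    k = cfg.max_knockouts if cfg.representation == "fixed" else rng.randint(1, cfg.max_knockouts)
    k = min(k, len(pool))
    return frozenset(rng.sample(list(pool), k))


def _mutate(
    rng: random.Random, sol: frozenset, pool: Sequence[str], cfg: MetaheuristicConfig
) -> frozenset:
    out = set(sol)
    moves = ["replace"]
    if cfg.representation == "variable":
        if len(out) < cfg.max_knockouts:
            moves.append("add")
        if len(out) > 1:
            moves.append("remove")
    move = rng.choice(moves)
    free = [c for c in pool if c not in out]
    if move == "replace" and out and free:
        out.remove(rng.choice(sorted(out)))
        out.add(rng.choice(free))
    elif move == "add" and free:
        out.add(rng.choice(free))
    elif move == "remove" and len(out) > 1:
        out.remove(rng.choice(sorted(out)))
    return frozenset(out) if out else frozenset({rng.choice(list(pool))})


def _crossover(rng: random.Random, a: frozenset, b: frozenset, cfg: MetaheuristicConfig) -> frozenset:
    """Uniform set crossover: shared elements kept, others inherited at random."""
    union = sorted(a | b)
    child = {e for e in union if e in a and e in b}
    for e in union:
        if e not in child and rng.random() < 0.5:
            child.add(e)
    child = set(sorted(child)[: cfg.max_knockouts]) if len(child) > cfg.max_knockouts else child
    if not child:
        child = {rng.choice(union)}
    if cfg.representation == "fixed":
        pool_fill = [e for e in union if e not in child]
        rng.shuffle(pool_fill)
        while len(child) < min(cfg.max_knockouts, len(union)) and pool_fill:
            child.add(pool_fill.pop())
    return frozenset(child)


def metaheuristic_optimize(
    model: MetabolicModel,
    spec: ObjectiveSpec,
    cfg: MetaheuristicConfig,
    env: Optional[EnvironmentalConditions] = None,
    excluded: Optional[EssentialitySet] = None,
) -> List[KnockoutSolution]:
    """Search knockout sets with an EA or SA; returns distinct solutions
    ranked by descending score.

    Every evaluation is a full phenotype simulation followed by the
    objective; results are memoized, and the run is fully reproducible from
    ``cfg.seed``.  Essential reactions/genes in ``excluded`` are never used
    as targets.
    """
    pool = _candidates(model, spec, cfg.target_level, excluded)
    rng = random.Random(cfg.seed)
    ev = _Evaluator(model, spec, cfg, env)

    if cfg.strategy == "EA":
        _run_ea(rng, ev, pool, cfg)
    else:
        _run_sa(rng, ev, pool, cfg)

    ranked = sorted(
        ev.cache.values(), key=lambda s: (-s.score, sorted(s.deletions))
    )
    if not ranked or ranked[0].score <= 0.0:
        wt = ev(frozenset())
        ranked = sorted(
            ev.cache.values(), key=lambda s: (-s.score, sorted(s.deletions))
        )
    return ranked


def _initial_population(rng, pool, cfg: MetaheuristicConfig) -> list:
    """Random individuals, kept distinct while the pool allows it."""
    popn, seen = [], set()
    attempts = 0
    while len(popn) < cfg.population_size:
        ind = _random_set(rng, pool, cfg)
        attempts += 1
        if ind in seen and attempts < 10 * cfg.population_size:
            continue
        seen.add(ind)
        popn.append(ind)
    return popn


def _run_ea(rng, ev: _Evaluator, pool, cfg: MetaheuristicConfig) -> None:
    popn = _initial_population(rng, pool, cfg)
    scored = [(ev(ind).score, ind) for ind in popn]
    while ev.evaluations < cfg.evaluation_budget:
        scored.sort(key=lambda t: -t[0])
        nxt = [ind for _, ind in scored[: cfg.elitism]]
        while len(nxt) < cfg.population_size:
            a = _tournament(rng, scored, cfg.tournament_size)
            if rng.random() < cfg.crossover_rate:
                b = _tournament(rng, scored, cfg.tournament_size)
                child = _crossover(rng, a, b, cfg)
            else:
                child = a
            if rng.random() < max(cfg.mutation_rate * len(child), cfg.mutation_rate):
                child = _mutate(rng, child, pool, cfg)
            nxt.append(child)
        scored = [(ev(ind).score, ind) for ind in nxt]


def _tournament(rng, scored, size) -> frozenset:
    picks = [scored[rng.randrange(len(scored))] for _ in range(size)]
    return max(picks, key=lambda t: t[0])[1]


def _run_sa(rng, ev: _Evaluator, pool, cfg: MetaheuristicConfig) -> None:
    current = _random_set(rng, pool, cfg)
    cur_score = ev(current).score
    # initial temperature: accept the median early uphill move with p ~ 0.5
    probe = [abs(ev(_mutate(rng, current, pool, cfg)).score - cur_score) for _ in range(5)]
    probe = [p for p in probe if p > 0]
    temp = (sorted(probe)[len(probe) // 2] / np.log(2)) if probe else 1.0
    while ev.evaluations < cfg.evaluation_budget:
        cand = _mutate(rng, current, pool, cfg)
        sc = ev(cand).score
        delta = sc - cur_score
        if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-12)):
            current, cur_score = cand, sc
        temp *= cfg.cooling_factor


def optknock(
    model: MetabolicModel,
    product: str,
    max_knockouts: int,
    env: Optional[EnvironmentalConditions] = None,
    excluded: Optional[EssentialitySet] = None,
    min_biomass: Optional[float] = None,
    dual_bound: float = 1000.0,
) -> KnockoutSolution:
    """Bilevel knockout design reduced to a single-level MILP by LP duality.

    Maximizes the product flux over binary knockout choices y (at most
    ``max_knockouts`` deletions among non-essential candidates), subject to
    the flux vector being an *optimal* solution of the inner FBA problem
    (biomass maximization).  The reduction enforces inner primal
    feasibility, inner dual feasibility and the strong-duality equality;
    knockouts gate flux bounds through y, and the bilinear dual-times-y
    terms are linearized with McCormick envelopes using ``dual_bound``.

    ``min_biomass`` (default 5% of the wild-type optimum) excludes trivial
    zero-growth designs; pass 0 to disable.  The returned solution is
    re-simulated: biomass by inner FBA, product maximized over the inner
    optimum's alternate optima (the optimistic convention).
    """
    if model.biomass_reaction is None:
        raise ModelError("OptKnock needs a biomass reaction")
    if product not in model.reactions:
        raise ModelError(f"unknown product reaction {product!r}")
    if max_knockouts < 0:
        raise ValueError("max_knockouts must be >= 0")

    m = _prepare(model, env, None)
    wt = fba(model, env=env, with_shadow_prices=False)
    if not wt.ok:
        raise ModelError(f"wild-type FBA is {wt.status}")
    if min_biomass is None:
        min_biomass = config.VIABILITY_THRESHOLD * wt.objective_value

    bio = model.biomass_reaction
    if min_biomass > 0:
        r = m.reactions[bio]
        r.lower_bound = max(r.lower_bound, float(min_biomass))

    S, rows, cols = m.stoichiometric_matrix()
    n, mrows = len(cols), len(rows)
    lb = np.array([m.reactions[r].lower_bound for r in cols])
    ub = np.array([m.reactions[r].upper_bound for r in cols])
    c_inner = np.zeros(n)
    c_inner[cols.index(bio)] = 1.0

    spec_like = ObjectiveSpec(kind="YIELD", product=product, substrate=product)
    cand = [
        r
        for r in _candidates(model, spec_like, "reaction", excluded)
        if r != product and r != bio
    ]
    nc = len(cand)
    cand_ix = [cols.index(r) for r in cand]
    in_cand = np.zeros(n, bool)
    in_cand[cand_ix] = True

    # variables: v(n) | lam(m) | muU(n) | muL(n) | y(nc) | wU(nc) | wL(nc)
    ofs_v, ofs_l, ofs_u, ofs_w = 0, n, n + mrows, n + mrows + n
    ofs_y = n + mrows + 2 * n
    ofs_wu, ofs_wl = ofs_y + nc, ofs_y + 2 * nc
    ntot = ofs_y + 3 * nc

    D = dual_bound
    lo = np.concatenate([lb, -np.inf * np.ones(mrows), np.zeros(2 * n), np.zeros(3 * nc)])
    hi = np.concatenate([ub, np.inf * np.ones(mrows), D * np.ones(2 * n), np.ones(nc), D * np.ones(2 * nc)])
    # candidate primal bounds are gated by y via rows below, not the box
    lo[[ofs_v + j for j in cand_ix]] = np.minimum(lb[cand_ix], 0.0)
    hi[[ofs_v + j for j in cand_ix]] = np.maximum(ub[cand_ix], 0.0)

    rows_A: List = []
    lo_b: List[float] = []
    hi_b: List[float] = []

    def add(coefs: Dict[int, float], lo_v: float, hi_v: float):
        rows_A.append(coefs)
        lo_b.append(lo_v)
        hi_b.append(hi_v)

    # primal: S v = 0
    for i in range(mrows):
        add({ofs_v + j: S[i, j] for j in range(n) if S[i, j] != 0}, 0.0, 0.0)
    # candidate primal bounds gated by y: lb*y <= v <= ub*y
    for k, j in enumerate(cand_ix):
        add({ofs_v + j: 1.0, ofs_y + k: -ub[j]}, -np.inf, 0.0)
        add({ofs_v + j: 1.0, ofs_y + k: -lb[j]}, 0.0, np.inf)
    # dual feasibility: S' lam + muU - muL = c_inner
    for j in range(n):
        coefs = {ofs_l + i: S[i, j] for i in range(mrows) if S[i, j] != 0}
        coefs[ofs_u + j] = 1.0
        coefs[ofs_w + j] = -1.0
        add(coefs, c_inner[j], c_inner[j])
    # strong duality: c'v = sum_j ub_j*(muU_j or wU_j) - lb_j*(muL_j or wL_j)
    sd: Dict[int, float] = {ofs_v + cols.index(bio): 1.0}
    for j in range(n):
        if in_cand[j]:
            k = cand_ix.index(j)
            sd[ofs_wu + k] = sd.get(ofs_wu + k, 0.0) - ub[j]
            sd[ofs_wl + k] = sd.get(ofs_wl + k, 0.0) + lb[j]
        else:
            sd[ofs_u + j] = sd.get(ofs_u + j, 0.0) - ub[j]
            sd[ofs_w + j] = sd.get(ofs_w + j, 0.0) + lb[j]
    add(sd, 0.0, 0.0)
    # McCormick: w = y * mu with mu in [0, D], y binary
    for k, j in enumerate(cand_ix):
        for w_of, mu_of in ((ofs_wu, ofs_u), (ofs_wl, ofs_w)):
            add({w_of + k: 1.0, ofs_y + k: -D}, -np.inf, 0.0)          # w <= D y
            add({w_of + k: 1.0, mu_of + j: -1.0}, -np.inf, 0.0)       # w <= mu
            add({w_of + k: 1.0, mu_of + j: -1.0, ofs_y + k: -D}, -D, np.inf)  # w >= mu - D(1-y)
    # knockout budget: sum (1 - y) <= K
    add({ofs_y + k: -1.0 for k in range(nc)}, -np.inf, max_knockouts - nc)

    A = sp.lil_matrix((len(rows_A), ntot))
    for i, coefs in enumerate(rows_A):
        for j, v in coefs.items():
            A[i, j] = v
    obj = np.zeros(ntot)
    obj[ofs_v + cols.index(product)] = 1.0
    integrality = np.zeros(ntot)
    integrality[ofs_y : ofs_y + nc] = 1
    res = solve_milp(
        obj,
        [LinearConstraint(A.tocsc(), np.array(lo_b), np.array(hi_b))],
        integrality,
        Bounds(lo, hi),
        maximize=True,
    )
    if res.status != "optimal":
        raise ModelError(
            f"OptKnock MILP terminated with status {res.status!r}; this can "
            "indicate numerical instability -- try a smaller candidate set or "
            "a different dual_bound"
        )
    y = res.x[ofs_y : ofs_y + nc]
    deletions = frozenset(cand[k] for k in range(nc) if y[k] < 0.5)

    # report at the optimistic inner-optimal point: fix biomass at the inner
    # optimum, then maximize product among the alternate optima
    inner = fba(model, env=env, knockouts=set(deletions), with_shadow_prices=False)
    if not inner.ok:
        raise ModelError("OptKnock deletions give an infeasible inner problem")
    m_ko = _prepare(model, env, set(deletions))
    if min_biomass > 0:
        m_ko.reactions[bio].lower_bound = max(
            m_ko.reactions[bio].lower_bound, float(min_biomass)
        )
    best_prod = _lp_extreme(m_ko, product, True, extra_eq=[(bio, inner.objective_value)])
    milp_prod = float(res.x[ofs_v + cols.index(product)])
    if best_prod is None or abs(best_prod - milp_prod) > 1e-4 * max(1.0, abs(milp_prod)):
        raise ModelError(
            "OptKnock verification failed: the MILP product flux "
            f"({milp_prod:.6g}) disagrees with the re-simulated optimum "
            f"({best_prod}); numerical instability in the duality reduction"
        )
    return KnockoutSolution(
        deletions=deletions,
        score=float(best_prod),
        biomass_flux=float(inner.objective_value),
        product_flux=float(best_prod),
        simulation=inner,
    )
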