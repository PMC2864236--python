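"""Phenotype simulation: FBA, MOMA and ROOM.

FBA (flux balance analysis) solves the linear program

    optimize  c.v   subject to   S.v = 0,  lb <= v <= ub

where c selects the objective flux (the biomass reaction by default).
Mutants are simulated by closing knocked-out reactions to (0, 0).

MOMA (minimization of metabolic adjustment) predicts a knockout phenotype as
the feasible mutant flux vector of minimum squared Euclidean distance to a
wild-type reference distribution -- the premise being that regulation does
not instantly re-optimize growth after a perturbation.

ROOM (regulatory on/off minimization) instead minimizes the *number* of
fluxes that change significantly relative to the reference: a binary y_j
marks reaction j as changed whenever v_j leaves the tolerance band
[w_j - delta|w_j| - eps, w_j + delta|w_j| + eps].  Both the exact MILP and
its LP relaxation are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Set

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint

from . import config
from ._solvers import solve_lp, solve_milp, solve_qp
from .model import (
    EnvironmentalConditions,
    MetabolicModel,
    ModelError,
    SimulationResult,
    apply_environmental_conditions,
    apply_knockouts,
    net_conversion,
)


@dataclass(frozen=True)
class RoomParameters:
    """ROOM tolerance band: delta is relative, epsilon absolute (flux units).

    Defaults follow the method's original publication.
    """

    delta: float = 0.03
    epsilon: float = 0.001
    relaxed: bool = False

    def __post_init__(self):
        if self.delta < 0 or self.epsilon < 0:
            raise ValueError("ROOM tolerances must be non-negative")


@dataclass(frozen=True)
class ReferenceFluxes:
    """Wild-type flux distribution MOMA/ROOM measure distances against."""

    fluxes: Dict[str, float]
    source: str = "user-supplied"  # or "fba"


def _prepare(
    model: MetabolicModel,
    env: Optional[EnvironmentalConditions],
    knockouts: Optional[Set[str]],
) -> MetabolicModel:
    m = model
    if env is not None:
        m = apply_environmental_conditions(m, env)
    if knockouts:
        m = apply_knockouts(m, set(knockouts))
    elif env is None:
        m = m.copy()
    return m


def fba(
    model: MetabolicModel,
    objective_reaction: Optional[str] = None,
    direction: str = "max",
    env: Optional[EnvironmentalConditions] = None,
    knockouts: Optional[Set[str]] = None,
    with_shadow_prices: bool = True,
) -> SimulationResult:
    """Flux balance analysis.

    Maximizes (or minimizes) the objective flux over the steady-state
    polytope.  Shadow prices are the duals of the metabolite balance rows,
    signed so that a positive value means an extra unit of external supply
    of that metabolite would increase the objective.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    obj = objective_reaction or model.biomass_reaction
    if obj is None:
        raise ModelError("no objective: model has no biomass reaction and none was given")
    if obj not in model.reactions:
        raise ModelError(f"objective reaction {obj!r} not in model")

    m = _prepare(model, env, knockouts)
    S, rows, cols = m.stoichiometric_matrix()
    c = np.zeros(len(cols))
    c[cols.index(obj)] = 1.0
    bounds = [(m.reactions[r].lower_bound, m.reactions[r].upper_bound) for r in cols]
    res = solve_lp(c, S, np.zeros(len(rows)), bounds, maximize=(direction == "max"))

    if res.status != "optimal":
        return SimulationResult(
            fluxes={}, method="FBA", objective_reaction=obj, objective_value=None,
            status=res.status, knockouts=set(knockouts or set()),
        )
    fluxes = dict(zip(cols, (float(v) for v in res.x)))
    shadow = None
    if with_shadow_prices and res.eq_duals is not None:
        # eq_duals = dZ*/db for S.v = b; supplying one unit of metabolite i
        # from outside corresponds to b_i = -1, hence the sign flip.
        shadow = {mid: float(-d) for mid, d in zip(rows, res.eq_duals)}
    return SimulationResult(
        fluxes=fluxes,
        method="FBA",
        objective_reaction=obj,
        objective_value=float(res.objective),
        status="optimal",
        knockouts=set(knockouts or set()),
        net_conversion=net_conversion(m, fluxes),
        shadow_prices=shadow,
    )


def wild_type_reference(
    model: MetabolicModel, env: Optional[EnvironmentalConditions] = None
) -> ReferenceFluxes:
    """FBA wild-type solution packaged as a MOMA/ROOM reference.

    FBA optima can be degenerate, so for reproducible comparisons the
    reference should be stored alongside any result derived from it.
    """
    res = fba(model, env=env, with_shadow_prices=False)
    if not res.ok:
        raise ModelError(f"wild-type FBA is {res.status}; cannot build a reference")
    return ReferenceFluxes(fluxes=res.fluxes, source="fba")


def _check_reference(model: MetabolicModel, reference: ReferenceFluxes) -> np.ndarray:
    missing = set(model.reactions) - set(reference.fluxes)
    if missing:
        raise ModelError(f"reference misses fluxes for {sorted(missing)}")
    return np.array([reference.fluxes[r] for r in model.reaction_ids], float)


def moma(
    model: MetabolicModel,
    reference: Optional[ReferenceFluxes] = None,
    knockouts: Optional[Set[str]] = None,
    env: Optional[EnvironmentalConditions] = None,
) -> SimulationResult:
    """Minimization of metabolic adjustment (convex QP).

    Returns the mutant flux vector minimizing sum_j (v_j - w_j)^2 subject to
    steady state and the mutant bounds.  ``objective_value`` is the biomass
    flux at the minimizer (when a biomass reaction is set); the squared
    distance is reported in ``metrics["distance_sq"]``.
    """
    if reference is None:
        reference = wild_type_reference(model, env)
    w = _check_reference(model, reference)
    m = _prepare(model, env, knockouts)
    S, rows, cols = m.stoichiometric_matrix()
    bounds = [(m.reactions[r].lower_bound, m.reactions[r].upper_bound) for r in cols]
    n = len(cols)
    res = solve_qp(2.0 * np.eye(n), -2.0 * w, S, np.zeros(len(rows)), bounds)

    obj_rid = model.biomass_reaction
    if res.status != "optimal":
        return SimulationResult(
            fluxes={}, method="MOMA", objective_reaction=obj_rid, objective_value=None,
            status=res.status, knockouts=set(knockouts or set()),
        )
    fluxes = dict(zip(cols, (float(v) for v in res.x)))
    dist_sq = float(np.sum((res.x - w) ** 2))
    return SimulationResult(
        fluxes=fluxes,
        method="MOMA",
        objective_reaction=obj_rid,
        objective_value=fluxes[obj_rid] if obj_rid else None,
        status="optimal",
        knockouts=set(knockouts or set()),
        net_conversion=net_conversion(m, fluxes),
        metrics={"distance_sq": dist_sq},
    )


def room(
    model: MetabolicModel,
    reference: Optional[ReferenceFluxes] = None,
    knockouts: Optional[Set[str]] = None,
    params: RoomParameters = RoomParameters(),
    env: Optional[EnvironmentalConditions] = None,
) -> SimulationResult:
    """Regulatory on/off minimization (MILP, or its LP relaxation).

    Minimizes the number of significantly changed fluxes.  Big-M constants
    are derived per reaction from its own bounds, never from a global
    constant.  ``metrics["changes"]`` holds the optimal change count (a
    fractional value for the relaxation).
    """
    if reference is None:
        reference = wild_type_reference(model, env)
    w = _check_reference(model, reference)
    m = _prepare(model, env, knockouts)
    S, rows, cols = m.stoichiometric_matrix()
    n = len(cols)
    lb = np.array([m.reactions[r].lower_bound for r in cols])
    ub = np.array([m.reactions[r].upper_bound for r in cols])
    wu = w + params.delta * np.abs(w) + params.epsilon
    wl = w - params.delta * np.abs(w) - params.epsilon

    # variables: [v (n), y (n)]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sp.hstack([sp.csc_matrix(S), sp.csc_matrix((len(rows), n))])
    eye = sp.eye(n, format="csc")
    # v_j - (ub_j - wu_j) y_j <= wu_j  (y=1 relaxes the cap to ub_j)
    A_up = sp.hstack([eye, -sp.diags(ub - wu)])
    # v_j - (lb_j - wl_j) y_j >= wl_j  (y=1 relaxes the floor to lb_j)
    A_lo = sp.hstack([eye, -sp.diags(lb - wl)])
    constraints = [
        LinearConstraint(A_eq, 0.0, 0.0),
        LinearConstraint(A_up, -np.inf, wu),
        LinearConstraint(A_lo, wl, np.inf),
    ]
    var_bounds = Bounds(
        np.concatenate([lb, np.zeros(n)]), np.concatenate([ub, np.ones(n)])
    )
    integrality = np.concatenate(
        [np.zeros(n), np.zeros(n) if params.relaxed else np.ones(n)]
    )
    res = solve_milp(c, constraints, integrality, var_bounds)

    method = "ROOM-LP" if params.relaxed else "ROOM"
    obj_rid = model.biomass_reaction
    if res.status != "optimal":
        return SimulationResult(
            fluxes={}, method=method, objective_reaction=obj_rid, objective_value=None,
            status=res.status, knockouts=set(knockouts or set()),
        )
    v = res.x[:n]
    y = res.x[n:]
    fluxes = dict(zip(cols, (float(x) for x in v)))
    changes = float(np.sum(y)) if params.relaxed else int(round(float(np.sum(y))))
    return SimulationResult(
        fluxes=fluxes,
        method=method,
        objective_reaction=obj_rid,
        objective_value=fluxes[obj_rid] if obj_rid else None,
        status="optimal",
        knockouts=set(knockouts or set()),
        net_conversion=net_conversion(m, fluxes),
        metrics={"changes": changes},
    )
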