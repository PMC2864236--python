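"""Flux variability analysis and metabolic flux analysis.

FVA computes per-reaction flux envelopes: either the maximum of one target
flux along a grid of fixed biomass values (a production-vs-growth trade-off
curve), or tight (min, max) bounds for every reaction under a minimum-biomass
constraint and optional measured-flux equalities.

MFA takes experimentally measured fluxes, splits the steady-state system
S.v = 0 into measured and unknown parts, classifies it by the rank of the
unknown submatrix, and solves it: exactly when determined, by least squares
when overdetermined (the residual norm measures data consistency), and by
FBA with the measurements pinned when underdetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import config
from ._solvers import solve_lp
from .model import (
    EnvironmentalConditions,
    MetabolicModel,
    ModelError,
    SimulationResult,
    net_conversion,
)
from .simulation import _prepare, fba


@dataclass
class FluxBounds:
    """Per-reaction (min, max) flux envelope."""

    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi + 1e-9:
                raise ModelError(f"flux bounds for {rid!r}: min {lo} > max {hi}")

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.bounds[rid]

    def __iter__(self):
        return iter(self.bounds)


@dataclass(frozen=True)
class MeasuredFluxes:
    """Experimentally measured flux values, with optional standard deviations."""

    values: Dict[str, float]
    sd: Optional[Dict[str, float]] = None

    def validate(self, model: MetabolicModel) -> None:
        for rid, v in self.values.items():
            if rid not in model.reactions:
                raise ModelError(f"measured flux names unknown reaction {rid!r}")
            r = model.reactions[rid]
            if not (r.lower_bound - 1e-9 <= v <= r.upper_bound + 1e-9):
                raise ModelError(
                    f"measured flux {rid!r}={v} outside model bounds "
                    f"[{r.lower_bound}, {r.upper_bound}]"
                )


@dataclass(frozen=True)
class MfaClassification:
    kind: str  # "underdetermined" | "determined" | "overdetermined"
    rank: int  # rank of the unknown-flux submatrix
    degrees_of_freedom: int
    n_unknown: int
    n_equations: int  # independent balance equations in the full system


def _lp_extreme(
    m: MetabolicModel,
    target: str,
    maximize: bool,
    extra_eq: Optional[List[Tuple[str, float]]] = None,
) -> Optional[float]:
    """Optimize one flux subject to steady state plus flux-pinning equalities."""
    S, rows, cols = m.stoichiometric_matrix()
    n = len(cols)
    c = np.zeros(n)
    c[cols.index(target)] = 1.0
    A = S
    b = np.zeros(len(rows))
    if extra_eq:
        pins = np.zeros((len(extra_eq), n))
        vals = np.zeros(len(extra_eq))
        for i, (rid, v) in enumerate(extra_eq):
            pins[i, cols.index(rid)] = 1.0
            vals[i] = v
        A = np.vstack([S, pins])
        b = np.concatenate([b, vals])
    bounds = [(m.reactions[r].lower_bound, m.reactions[r].upper_bound) for r in cols]
    res = solve_lp(c, A, b, bounds, maximize=maximize)
    return None if res.status != "optimal" else float(res.objective)


def fva_target_vs_biomass(
    model: MetabolicModel,
    target: str,
    n_steps: int,
    env: Optional[EnvironmentalConditions] = None,
) -> List[Tuple[float, Optional[float]]]:
    """Maximum target flux along a biomass grid from 0 to the wild-type optimum.

    The biomass flux is pinned by equality at each of ``n_steps`` evenly
    spaced grid values (endpoints included).  Grid points that turn out
    infeasible numerically are flagged with a None maximum, not dropped.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if model.biomass_reaction is None:
        raise ModelError("flux-vs-biomass analysis needs a biomass reaction")
    if target not in model.reactions:
        raise ModelError(f"unknown target reaction {target!r}")
    wt = fba(model, env=env, with_shadow_prices=False)
    if not wt.ok:
        raise ModelError(f"wild-type FBA is {wt.status}")
    m = _prepare(model, env, None)
    grid = np.linspace(0.0, wt.objective_value, n_steps)
    out = []
    for b in grid:
        vmax = _lp_extreme(m, target, True, extra_eq=[(model.biomass_reaction, float(b))])
        out.append((float(b), vmax))
    return out


def fva_tight_bounds(
    model: MetabolicModel,
    min_biomass: float = 0.0,
    env: Optional[EnvironmentalConditions] = None,
    measured: Optional[MeasuredFluxes] = None,
) -> FluxBounds:
    """Tight (min, max) bounds for every flux, via 2n LP solves.

    Constraints: steady state, model bounds, biomass >= ``min_biomass`` (when
    a biomass reaction is set and the floor is positive) and any measured
    fluxes pinned by equality.
    """
    if min_biomass < 0:
        raise ValueError("min_biomass must be >= 0")
    m = _prepare(model, env, None)
    pins: List[Tuple[str, float]] = []
    if measured is not None:
        measured.validate(model)
        pins = list(measured.values.items())
    if min_biomass > 0:
        if model.biomass_reaction is None:
            raise ModelError("min_biomass > 0 requires a biomass reaction")
        r = m.reactions[model.biomass_reaction]
        r.lower_bound = max(r.lower_bound, float(min_biomass))
    out: Dict[str, Tuple[float, float]] = {}
    for rid in m.reaction_ids:
        lo = _lp_extreme(m, rid, False, extra_eq=pins or None)
        hi = _lp_extreme(m, rid, True, extra_eq=pins or None)
        if lo is None or hi is None:
            raise ModelError(
                "tight-bounds constraints are infeasible: the minimum-biomass "
                "requirement conflicts with the measured fluxes or model bounds"
            )
        out[rid] = (lo, hi)
    return FluxBounds(out)


def _split(model: MetabolicModel, measured: MeasuredFluxes):
    S, rows, cols = model.stoichiometric_matrix()
    meas_ids = [r for r in cols if r in measured.values]
    unk_ids = [r for r in cols if r not in measured.values]
    Sm = S[:, [cols.index(r) for r in meas_ids]]
    Su = S[:, [cols.index(r) for r in unk_ids]]
    vm = np.array([measured.values[r] for r in meas_ids])
    return S, Su, Sm, vm, unk_ids, meas_ids


def mfa_classify(model: MetabolicModel, measured: MeasuredFluxes) -> MfaClassification:
    """Classify the MFA system by comparing equations against unknowns.

    With more independent balance equations than unknown fluxes the system
    is overdetermined (redundant, solvable in the least-squares sense); with
    exactly enough it is determined; otherwise underdetermined.
    """
    if not measured.values:
        raise ModelError("MFA needs at least one measured flux")
    measured.validate(model)
    S, Su, Sm, vm, unk_ids, _ = _split(model, measured)
    n_unknown = Su.shape[1]
    rank_u = int(np.linalg.matrix_rank(Su)) if n_unknown else 0
    n_eq = int(np.linalg.matrix_rank(S))
    dof = n_unknown - rank_u
    if n_eq > n_unknown:
        kind = "overdetermined"
    elif dof == 0:
        kind = "determined"
    else:
        kind = "underdetermined"
    return MfaClassification(
        kind=kind, rank=rank_u, degrees_of_freedom=dof,
        n_unknown=n_unknown, n_equations=n_eq,
    )


def mfa_solve(
    model: MetabolicModel,
    measured: MeasuredFluxes,
    objective: Optional[str] = None,
) -> SimulationResult:
    """Solve for the unknown fluxes given the measured ones.

    determined      exact linear solve of S_u.v_u = -S_m.v_m
    overdetermined  least squares via the pseudo-inverse; the residual norm
                    ||S_u.v_u + S_m.v_m|| (inverse-variance weighted when
                    standard deviations are given) measures consistency
    underdetermined FBA with measured fluxes fixed as equalities, objective
                    defaulting to the biomass reaction
    """
    cls = mfa_classify(model, measured)
    S, Su, Sm, vm, unk_ids, meas_ids = _split(model, measured)

    if cls.kind == "underdetermined":
        obj = objective or model.biomass_reaction
        if obj is None:
            raise ModelError("underdetermined MFA needs an objective reaction")
        m = model.copy()
        for rid, v in measured.values.items():
            m.reactions[rid].lower_bound = float(v)
            m.reactions[rid].upper_bound = float(v)
        res = fba(m, objective_reaction=obj)
        res.method = "MFA-FBA"
        res.metrics["classification"] = cls.kind
        return res

    rhs = -Sm @ vm
    if cls.kind == "overdetermined" and measured.sd:
        # inverse-variance weighting of each balance row by the measurement
        # noise it inherits: var_i = sum_j S_m[i,j]^2 sd_j^2
        sd = np.array([measured.sd.get(r, 1.0) for r in meas_ids])
        row_var = (Sm ** 2) @ (sd ** 2)
        wgt = 1.0 / np.sqrt(np.where(row_var > 0, row_var, 1.0))
        vu, *_ = np.linalg.lstsq(Su * wgt[:, None], rhs * wgt, rcond=None)
    else:
        vu, *_ = np.linalg.lstsq(Su, rhs, rcond=None)
    residual = float(np.linalg.norm(Su @ vu - rhs))
    if cls.kind == "determined" and residual > 1e-6 * max(1.0, float(np.linalg.norm(rhs))):
        raise ModelError(
            f"determined MFA system is numerically inconsistent (residual {residual:.3g})"
        )
    fluxes = dict(measured.values)
    fluxes.update({rid: float(v) for rid, v in zip(unk_ids, vu)})
    obj_rid = objective or model.biomass_reaction
    return SimulationResult(
        fluxes=fluxes,
        method="MFA",
        objective_reaction=obj_rid,
        objective_value=fluxes.get(obj_rid) if obj_rid else None,
        status="optimal",
        net_conversion=net_conversion(model, fluxes),
        metrics={"residual": residual, "classification": cls.kind},
    )
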