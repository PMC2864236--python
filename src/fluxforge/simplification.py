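"""Model reduction and essentiality screening.

Structural simplification works on the exact rational nullspace of the
internal stoichiometric matrix and is therefore valid under *every*
environmental condition: reactions whose nullspace row is zero can never
carry flux (structurally blocked), and reactions whose nullspace rows are
proportional always carry fluxes in a fixed ratio (enzyme subsets) and can
be merged into a single representative.

Simulation-based reduction instead tightens every reaction's bounds to its
FVA envelope under given environmental conditions, flagging reactions whose
envelope collapses to zero.

Essentiality screening deletes one reaction (or gene) at a time and calls
the mutant non-viable when its FBA biomass drops below a fraction of the
wild-type optimum (5% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Set, Tuple

import sympy

from . import config
from .model import (
    EnvironmentalConditions,
    MetabolicModel,
    ModelError,
    apply_knockouts,
    genes_to_reactions,
)
from .simulation import fba
from .variability import fva_tight_bounds


@dataclass(frozen=True)
class EquivalentGroup:
    """Reactions whose steady-state fluxes are always proportional.

    ``ratios`` maps each member to the rational factor r with
    v_member = r * v_representative in every steady-state flux vector; the
    representative has ratio 1.  Ratios are signed: a negative ratio means
    the members always run in opposite directions.
    """

    members: frozenset
    representative: str
    ratios: Dict[str, Fraction] = field(hash=False, default_factory=dict)


@dataclass(frozen=True)
class EssentialitySet:
    level: str  # "reaction" | "gene"
    essential: frozenset
    wild_type_biomass: float
    threshold: float


def _exact_nullspace_rows(model: MetabolicModel) -> Tuple[Dict[str, tuple], int]:
    """Rows (one per reaction) of an exact rational nullspace basis of S."""
    S, rows, cols = model.stoichiometric_matrix()
    M = sympy.Matrix([[sympy.Rational(x) for x in row] for row in S.tolist()])
    basis = M.nullspace()
    dim = len(basis)
    out: Dict[str, tuple] = {}
    for j, rid in enumerate(cols):
        out[rid] = tuple(Fraction(int(v[j].p), int(v[j].q)) for v in basis)
    return out, dim


def structural_zero_reactions(model: MetabolicModel) -> Set[str]:
    """Reactions whose flux is zero in every steady-state flux vector.

    Computed from the exact nullspace of S, so the answer is independent of
    bounds and environmental conditions.
    """
    rows, _ = _exact_nullspace_rows(model)
    return {rid for rid, row in rows.items() if all(x == 0 for x in row)}


def equivalent_reaction_groups(model: MetabolicModel) -> List[EquivalentGroup]:
    """Group reactions with proportional nullspace rows (enzyme subsets).

    Structurally-blocked reactions are excluded.  Groups are returned in
    model reaction order, each with exact rational flux ratios relative to
    its first member.
    """
    rows, dim = _exact_nullspace_rows(model)
    if dim == 0:
        return []
    buckets: Dict[tuple, List[Tuple[str, Fraction]]] = {}
    for rid in model.reaction_ids:
        row = rows[rid]
        lead = next((x for x in row if x != 0), None)
        if lead is None:
            continue  # structurally blocked
        key = tuple(x / lead for x in row)
        buckets.setdefault(key, []).append((rid, lead))
    groups = []
    for members in buckets.values():
        if len(members) < 2:
            continue
        rep, rep_lead = members[0]
        ratios = {rid: lead / rep_lead for rid, lead in members}
        groups.append(
            EquivalentGroup(
                members=frozenset(r for r, _ in members),
                representative=rep,
                ratios=ratios,
            )
        )
    return groups


def reduce_model(
    model: MetabolicModel, env: Optional[EnvironmentalConditions] = None
) -> Tuple[MetabolicModel, Dict[str, dict]]:
    """Replace every reaction's bounds by its FVA envelope under ``env``.

    Reactions whose envelope is (0, 0) are marked removed in the provenance
    map (they stay in the model with closed bounds, keeping flux-vector
    dimensions stable).  Unlike structural analysis this reduction is only
    valid under the environmental conditions it was computed for.
    """
    tb = fva_tight_bounds(model, min_biomass=0.0, env=env)
    out = model.copy(name=f"{model.name}-reduced")
    provenance: Dict[str, dict] = {}
    tol = config.ZERO_TOL
    for rid in out.reaction_ids:
        old = (out.reactions[rid].lower_bound, out.reactions[rid].upper_bound)
        lo, hi = tb[rid]
        out.reactions[rid].lower_bound = lo
        out.reactions[rid].upper_bound = hi
        provenance[rid] = {
            "original_bounds": old,
            "reduced_bounds": (lo, hi),
            "removed": abs(lo) <= tol and abs(hi) <= tol,
        }
    return out, provenance


def find_essential(
    model: MetabolicModel,
    level: str = "reaction",
    env: Optional[EnvironmentalConditions] = None,
    threshold: float = config.VIABILITY_THRESHOLD,
) -> EssentialitySet:
    """Single-deletion essentiality screen by FBA.

    A deletion is essential when the mutant's maximal biomass flux falls
    below ``threshold`` times the wild-type optimum.  Gene-level screening
    maps each gene deletion through the GPR rules first.
    """
    if level not in ("reaction", "gene"):
        raise ValueError(f"level must be 'reaction' or 'gene', got {level!r}")
    if not 0 < threshold < 1:
        raise ValueError("viability threshold must be in (0, 1)")
    if model.biomass_reaction is None:
        raise ModelError("essentiality screening needs a biomass reaction")
    wt = fba(model, env=env, with_shadow_prices=False)
    if not wt.ok or wt.objective_value <= config.ZERO_TOL:
        raise ModelError("wild-type biomass is ~0; the viability threshold is undefined")
    floor = threshold * wt.objective_value

    if level == "gene":
        if not model.genes:
            raise ModelError("gene-level screening needs gene-reaction rules")
        candidates = sorted(model.genes)
    else:
        candidates = model.reaction_ids

    essential = set()
    for cand in candidates:
        kos = genes_to_reactions(model, {cand}) if level == "gene" else {cand}
        if level == "gene" and not kos:
            continue
        mut = fba(model, env=env, knockouts=kos, with_shadow_prices=False)
        if not mut.ok or mut.objective_value < floor:
            essential.add(cand)
    return EssentialitySet(
        level=level,
        essential=frozenset(essential),
        wild_type_biomass=float(wt.objective_value),
        threshold=float(threshold),
    )
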