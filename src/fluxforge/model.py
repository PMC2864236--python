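"""In-memory representation of stoichiometric metabolic models.

A model is a set of metabolites (internal or external), a set of reactions
with flux bounds and stoichiometry, an optional designated biomass reaction
and an optional gene set with gene-protein-reaction (GPR) rules.  The
steady-state system S.v = 0 is defined over internal metabolites only;
external species sit outside the balanced system and show up in net
conversions (the overall external-metabolite balance of a flux vector).

Conventions
-----------
* Stoichiometric coefficients are signed: negative = consumed, positive =
  produced.
* Reversibility is encoded purely by bounds: a reaction is reversible iff
  its lower bound is negative.  There is no separate flag to fall out of
  sync.
* A knockout sets a reaction's bounds to (0, 0) rather than removing it, so
  flux vectors keep a fixed dimension across wild-type and mutants (MOMA and
  ROOM distances need aligned vectors).
* Drain (exchange) reactions touch exactly one internal metabolite.  A
  one-sided drain written as ``A ->`` is normalized at construction to carry
  an explicit external counterpart ``A_ext`` so that net conversions are a
  pure matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np

from . import config
from .gpr import GeneRule


class ModelError(ValueError):
    """Inconsistent model structure or an unknown identifier."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Optional[str] = None
    external: bool = False

    def __post_init__(self):
        if not self.id:
            raise ModelError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """One reaction: stoichiometry, flux bounds and an optional GPR rule."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = config.DEFAULT_BOUND
    name: str = ""
    gene_rule: Optional[GeneRule] = None
    is_drain: bool = False  # set by the owning model

    def __post_init__(self):
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        # LP layers need finite big-M values; clip infinities at load.
        M = config.DEFAULT_BOUND
        self.lower_bound = float(np.clip(self.lower_bound, -M, M))
        self.upper_bound = float(np.clip(self.upper_bound, -M, M))
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        r = Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gene_rule=self.gene_rule,
        )
        r.is_drain = self.is_drain
        return r


@dataclass(frozen=True)
class EnvironmentalConditions:
    """Bound overrides on drain reactions (e.g. nutrient availability).

    Typical use: close or limit the uptake of oxygen or a carbon source to
    emulate aerobic/anaerobic or substrate-limited growth.
    """

    overrides: Mapping[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for rid, (lb, ub) in self.overrides.items():
            if lb > ub:
                raise ModelError(f"environmental override for {rid!r}: lb {lb} > ub {ub}")


@dataclass
class SimulationResult:
    """Outcome of one phenotype simulation (FBA, MOMA or ROOM).

    ``objective_value`` is the flux through ``objective_reaction`` at the
    returned point; method-specific criteria (squared distance for MOMA,
    change count for ROOM) live in ``metrics``.
    """

    fluxes: Dict[str, float]
    method: str
    objective_reaction: Optional[str]
    objective_value: Optional[float]
    status: str  # "optimal" | "infeasible" | "unbounded"
    knockouts: Set[str] = field(default_factory=set)
    net_conversion: Dict[str, float] = field(default_factory=dict)
    shadow_prices: Optional[Dict[str, float]] = None
    metrics: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """A stoichiometric metabolic model.

    Parameters
    ----------
    metabolites, reactions:
        Ordered collections; ids must be unique.
    biomass_reaction:
        Id of the biomass-formation reaction, if designated.
    genes:
        Known gene ids.  Every gene referenced by a GPR rule must be listed.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction: Optional[str] = None,
        genes: Optional[Set[str]] = None,
        name: str = "",
    ):
        self.name = name
        self.metabolites: Dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        self.reactions: Dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            self.reactions[r.id] = r
        self.biomass_reaction = biomass_reaction
        self.genes: Set[str] = set(genes or set())
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        for r in self.reactions.values():
            for mid in r.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
            if r.gene_rule is not None:
                missing = r.gene_rule.genes - self.genes
                if missing:
                    raise ModelError(
                        f"reaction {r.id!r} GPR references unknown genes {sorted(missing)}"
                    )
        if self.biomass_reaction is not None and self.biomass_reaction not in self.reactions:
            raise ModelError(f"biomass reaction {self.biomass_reaction!r} not in model")
        self._normalize_drains()

    def _normalize_drains(self) -> None:
        """Flag drains and give one-sided drains an external counterpart.

        A drain touches exactly one internal metabolite (every other species
        being external).  A one-sided drain such as ``A ->`` gets an explicit
        external species ``A_ext`` added so that net conversions can be read
        straight off the stoichiometry.
        """
        for r in self.reactions.values():
            internal = [m for m in r.stoichiometry if not self.metabolites[m].external]
            r.is_drain = len(internal) == 1
            if r.is_drain and len(r.stoichiometry) == 1:
                mid = internal[0]
                ext_id = f"{mid}_ext"
                if ext_id not in self.metabolites:
                    self.metabolites[ext_id] = Metabolite(
                        id=ext_id, name=f"{mid} (external)", external=True
                    )
                elif not self.metabolites[ext_id].external:
                    raise ModelError(
                        f"cannot normalize drain {r.id!r}: {ext_id!r} exists and is internal"
                    )
                r.stoichiometry[ext_id] = -r.stoichiometry[mid]

    # -- views -------------------------------------------------------------

    @property
    def reaction_ids(self) -> list:
        return list(self.reactions)

    @property
    def internal_metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites.values() if not m.external]

    @property
    def external_metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites.values() if m.external]

    @property
    def drain_reaction_ids(self) -> list:
        return [r.id for r in self.reactions.values() if r.is_drain]

    def stoichiometric_matrix(self, external: bool = False) -> Tuple[np.ndarray, list, list]:
        """Dense S matrix, with its row (metabolite) and column (reaction) ids.

        By default rows are the internal metabolites, i.e. the rows of the
        steady-state system S.v = 0.
        """
        rows = self.external_metabolite_ids if external else self.internal_metabolite_ids
        cols = self.reaction_ids
        S = np.zeros((len(rows), len(cols)))
        row_ix = {m: i for i, m in enumerate(rows)}
        for j, rid in enumerate(cols):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                i = row_ix.get(mid)
                if i is not None:
                    S[i, j] = float(coef)
        return S, rows, cols

    def bounds(self) -> Dict[str, Tuple[float, float]]:
        return {r.id: (r.lower_bound, r.upper_bound) for r in self.reactions.values()}

    def copy(self, name: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites.values()),
            reactions=[r.copy() for r in self.reactions.values()],
            biomass_reaction=self.biomass_reaction,
            genes=set(self.genes),
            name=self.name if name is None else name,
        )

    def __eq__(self, other) -> bool:
        """Structural equality up to element ordering.

        Compares ids, external flags, stoichiometry, bounds, GPR rules,
        genes and the biomass designation.  Display annotations (names,
        compartment labels) are excluded: serialization formats that require
        a compartment fill in a default, which must not break round-trips.
        """
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        if set(self.metabolites) != set(other.metabolites):
            return False
        for mid, m in self.metabolites.items():
            if m.external != other.metabolites[mid].external:
                return False
        if set(self.reactions) != set(other.reactions):
            return False
        for rid, r in self.reactions.items():
            o = other.reactions[rid]
            if not np.isclose(r.lower_bound, o.lower_bound) or not np.isclose(
                r.upper_bound, o.upper_bound
            ):
                return False
            if set(r.stoichiometry) != set(o.stoichiometry):
                return False
            for mid, c in r.stoichiometry.items():
                if not np.isclose(float(c), float(o.stoichiometry[mid])):
                    return False
            if r.gene_rule != o.gene_rule:
                return False
        return self.biomass_reaction == other.biomass_reaction and self.genes == other.genes

    def __repr__(self):
        return (
            f"MetabolicModel({self.name!r}: {len(self.reactions)} reactions, "
            f"{len(self.internal_metabolite_ids)} internal / "
            f"{len(self.external_metabolite_ids)} external metabolites)"
        )


# -- elementary transformations -------------------------------------------


def apply_environmental_conditions(
    model: MetabolicModel, env: EnvironmentalConditions
) -> MetabolicModel:
    """Return a copy of ``model`` with drain bounds overridden by ``env``.

    Only drain reactions may be overridden -- environmental conditions model
    nutrient intake and secretion limits, not internal regulation.
    """
    out = model.copy()
    for rid, (lb, ub) in env.overrides.items():
        if rid not in out.reactions:
            raise ModelError(f"environmental condition names unknown reaction {rid!r}")
        r = out.reactions[rid]
        if not r.is_drain:
            raise ModelError(
                f"environmental condition targets non-drain reaction {rid!r}"
            )
        r.lower_bound = float(lb)
        r.upper_bound = float(ub)
    return out


def apply_knockouts(model: MetabolicModel, reactions: Set[str]) -> MetabolicModel:
    """Return a copy of ``model`` with the listed reactions closed to (0, 0)."""
    out = model.copy()
    for rid in reactions:
        if rid not in out.reactions:
            raise ModelError(f"knockout names unknown reaction {rid!r}")
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    return out


def genes_to_reactions(model: MetabolicModel, deleted_genes: Set[str]) -> Set[str]:
    """Reactions disabled when ``deleted_genes`` are knocked out.

    A reaction is disabled iff its GPR rule evaluates False with the deleted
    genes set to False and every other gene True.  Reactions without a rule
    are never disabled.
    """
    unknown = set(deleted_genes) - model.genes
    if unknown:
        raise ModelError(f"unknown genes {sorted(unknown)}")
    state = {g: False for g in deleted_genes}
    return {
        r.id
        for r in model.reactions.values()
        if r.gene_rule is not None and not r.gene_rule.evaluate(state)
    }


def net_conversion(
    model: MetabolicModel, fluxes: Mapping[str, float], tol: Optional[float] = None
) -> Dict[str, float]:
    """Overall external-metabolite balance of a flux vector.

    For each external metabolite m the net rate is sum_j S[m, j] * v_j over
    all reactions (drains included); entries below the zero tolerance are
    omitted.  Negative = net consumed, positive = net produced.
    """
    tol = config.ZERO_TOL if tol is None else tol
    missing = set(model.reactions) - set(fluxes)
    if missing:
        raise ModelError(f"flux distribution missing reactions {sorted(missing)}")
    out: Dict[str, float] = {}
    for mid in model.external_metabolite_ids:
        rate = 0.0
        for r in model.reactions.values():
            coef = r.stoichiometry.get(mid)
            if coef:
                rate += float(coef) * fluxes[r.id]
        if abs(rate) > tol:
            out[mid] = rate
    return out
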