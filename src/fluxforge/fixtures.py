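"""Canonical toy networks and a seeded random-network generator.

The five toy models are small enough that every analysis in the package has
a hand-checkable answer on them; the random generator produces seeded sparse
networks with a guaranteed uptake-to-biomass route, used for property and
oracle-equivalence testing without any external model files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel, Metabolite, ModelError, Reaction

TOY_NAMES = ("TOY-LIN", "TOY-BRANCH", "TOY-DIAMOND", "TOY-DEAD", "TOY-COUPLE")

_UB = 1000.0


def _met(mid: str, external: bool = False) -> Metabolite:
    return Metabolite(id=mid, name=mid, external=external)


def _rxn(rid: str, stoich: dict, lb: float = 0.0, ub: float = _UB) -> Reaction:
    return Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb, upper_bound=ub, name=rid)


def toy(name: str) -> MetabolicModel:
    """Return one of the canonical toy models.

    TOY-LIN      A_ext -> A -> B -> B_ext, a linear chain (biomass = R3,
                 uptake capped at 10).
    TOY-BRANCH   one uptake splitting into two secretions.
    TOY-DIAMOND  two parallel internal routes A -> B.
    TOY-DEAD     TOY-LIN plus a dead-end branch A -> C (C has no consumer).
    TOY-COUPLE   a route that couples biomass to by-product P secretion:
                 R2: A -> B competes with R3: 2A -> B + P.
    """
    if name == "TOY-LIN":
        return MetabolicModel(
            metabolites=[_met("A_ext", True), _met("A"), _met("B"), _met("B_ext", True)],
            reactions=[
                _rxn("R1", {"A_ext": -1, "A": 1}, ub=10),
                _rxn("R2", {"A": -1, "B": 1}),
                _rxn("R3", {"B": -1, "B_ext": 1}),
            ],
            biomass_reaction="R3",
            name=name,
        )
    if name == "TOY-BRANCH":
        return MetabolicModel(
            metabolites=[
                _met("A_ext", True), _met("A"), _met("B_ext", True), _met("C_ext", True),
            ],
            reactions=[
                _rxn("R1", {"A_ext": -1, "A": 1}, ub=10),
                _rxn("R2", {"A": -1, "B_ext": 1}),
                _rxn("R3", {"A": -1, "C_ext": 1}),
            ],
            name=name,
        )
    if name == "TOY-DIAMOND":
        return MetabolicModel(
            metabolites=[
                _met("A_ext", True), _met("A"), _met("B"), _met("BIOM_ext", True),
            ],
            reactions=[
                _rxn("R1", {"A_ext": -1, "A": 1}, ub=10),
                _rxn("R2", {"A": -1, "B": 1}),
                _rxn("R3", {"A": -1, "B": 1}),
                _rxn("R4", {"B": -1, "BIOM_ext": 1}),
            ],
            biomass_reaction="R4",
            name=name,
        )
    if name == "TOY-DEAD":
        return MetabolicModel(
            metabolites=[
                _met("A_ext", True), _met("A"), _met("B"), _met("B_ext", True), _met("C"),
            ],
            reactions=[
                _rxn("R1", {"A_ext": -1, "A": 1}, ub=10),
                _rxn("R2", {"A": -1, "B": 1}),
                _rxn("R3", {"B": -1, "B_ext": 1}),
                _rxn("R5", {"A": -1, "C": 1}),
            ],
            biomass_reaction="R3",
            name=name,
        )
    if name == "TOY-COUPLE":
        return MetabolicModel(
            metabolites=[
                _met("A_ext", True), _met("A"), _met("B"), _met("P"),
                _met("BIOM_ext", True), _met("P_ext", True),
            ],
            reactions=[
                _rxn("R1", {"A_ext": -1, "A": 1}, ub=10),
                _rxn("R2", {"A": -1, "B": 1}),
                _rxn("R3", {"A": -2, "B": 1, "P": 1}),
                _rxn("R4", {"B": -1, "BIOM_ext": 1}),
                _rxn("R5", {"P": -1, "P_ext": 1}),
            ],
            biomass_reaction="R4",
            name=name,
        )
    raise ModelError(f"unknown toy model {name!r}; choose from {TOY_NAMES}")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters for a seeded random network."""

    n_internal_metabolites: int = 4
    n_reactions: int = 8
    reversible_fraction: float = 0.0
    n_drains: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_internal_metabolites < 2 or self.n_reactions < 4 or self.n_drains < 2:
            raise ModelError(
                "random network needs >= 2 internal metabolites, >= 4 reactions "
                "and >= 2 drains (uptake + biomass)"
            )


def random_network(spec: FixtureSpec) -> MetabolicModel:
    """Seeded sparse random network with a working uptake-to-biomass route.

    Construction: a backbone chain M1 -> M2 -> ... -> Mk connects the uptake
    drain to the biomass drain, guaranteeing a nonzero steady-state flux;
    remaining reactions are random internal conversions with coefficients in
    {-2, -1, 1, 2}, a seeded fraction of them reversible, and extra drains on
    random internal metabolites.  Same spec => identical model.
    """
    from .simulation import fba  # local import to avoid a cycle

    for attempt in range(20):
        rng = np.random.default_rng((spec.seed, attempt))
        model = _build_random(spec, rng)
        res = fba(model)
        if res.ok and res.objective_value > 1e-9:
            return model
    raise ModelError(f"could not build a feasible network for {spec} after 20 attempts")


def _build_random(spec: FixtureSpec, rng: np.random.Generator) -> MetabolicModel:
    k = spec.n_internal_metabolites
    internal = [f"M{i+1}" for i in range(k)]
    mets = [_met("S_ext", True)] + [_met(m) for m in internal] + [_met("BIOM_ext", True)]

    reactions = [
        _rxn("R_up", {"S_ext": -1, internal[0]: 1}, ub=10),
        _rxn("R_bio", {internal[-1]: -1, "BIOM_ext": 1}),
    ]
    # backbone chain M1 -> ... -> Mk
    chain = [
        _rxn(f"R_c{i+1}", {internal[i]: -1, internal[i + 1]: 1}) for i in range(k - 1)
    ]
    reactions.extend(chain)

    n_extra_drains = spec.n_drains - 2
    n_random = spec.n_reactions - len(reactions) - n_extra_drains
    if n_random < 0:
        raise ModelError(
            f"n_reactions={spec.n_reactions} too small for {k} metabolites "
            f"and {spec.n_drains} drains (need >= {len(reactions) + n_extra_drains})"
        )

    ext_count = 0
    for d in range(n_extra_drains):
        m = internal[int(rng.integers(0, k))]
        ext_count += 1
        ext_id = f"X{ext_count}_ext"
        mets.append(_met(ext_id, True))
        reactions.append(_rxn(f"R_d{d+1}", {m: -1, ext_id: 1}))

    for i in range(n_random):
        ns = int(rng.integers(1, 3))
        np_ = int(rng.integers(1, 3))
        picks = rng.choice(k, size=min(ns + np_, k), replace=False)
        subs, prods = picks[:ns], picks[ns:]
        if len(prods) == 0:
            continue
        stoich: dict = {}
        for s in subs:
            stoich[internal[s]] = -int(rng.integers(1, 3))
        for p in prods:
            stoich[internal[p]] = int(rng.integers(1, 3))
        lb = -_UB if rng.random() < spec.reversible_fraction else 0.0
        reactions.append(_rxn(f"R_x{i+1}", stoich, lb=lb))

    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction="R_bio",
        name=f"random-{spec.seed}",
    )
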