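"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own solver paths: the LP
oracle goes through cobrapy/GLPK, and the elementary-mode oracle does
exhaustive support enumeration with exact rational nullspaces.  They exist
to cross-check the implementation, never to power it.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import gcd
from typing import List, Optional, Tuple

import pytest
import sympy

from fluxforge.fixtures import TOY_NAMES, FixtureSpec, random_network, toy
from fluxforge.model import MetabolicModel


@pytest.fixture(params=TOY_NAMES)
def toy_model(request) -> MetabolicModel:
    return toy(request.param)


def small_random_specs(n: int, max_reactions: int, seed0: int = 100, reversible: float = 0.0):
    """Deterministic family of generator specs for property tests."""
    specs = []
    for i in range(n):
        k = 2 + (i % 3)
        n_drains = 2 + (i % 2)
        base = (k - 1) + 2 + (n_drains - 2)  # backbone + uptake/biomass + extra drains
        specs.append(
            FixtureSpec(
                n_internal_metabolites=k,
                n_reactions=min(max_reactions, max(4, base + (i % 4))),
                reversible_fraction=reversible if i % 2 else 0.0,
                n_drains=n_drains,
                seed=seed0 + i,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# LP oracle (cobrapy + GLPK)


def cobra_fba_oracle(
    model: MetabolicModel, objective: Optional[str] = None, maximize: bool = True
):
    """FBA optimum via cobrapy/GLPK; returns (status, objective value)."""
    import cobra

    cm = cobra.Model(model.name or "m")
    cm.solver = "glpk"
    mets = {
        mid: cobra.Metabolite(mid)
        for mid in model.internal_metabolite_ids
    }
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites(
            {
                mets[mid]: float(c)
                for mid, c in r.stoichiometry.items()
                if mid in mets
            }
        )
        rxns.append(cr)
    cm.add_reactions(rxns)
    cm.objective = objective or model.biomass_reaction
    cm.objective_direction = "max" if maximize else "min"
    sol = cm.optimize()
    return sol.status, sol.objective_value


# ---------------------------------------------------------------------------
# elementary-mode oracle (exhaustive support enumeration)


def _normalize_int(vec: Tuple[Fraction, ...]) -> Tuple[Fraction, ...]:
    denoms = [c.denominator for c in vec if c != 0]
    if not denoms:
        return vec
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [c * lcm for c in vec]
    g = 0
    for c in ints:
        g = gcd(g, int(c))
    return tuple(c / g for c in ints) if g > 1 else tuple(ints)


def brute_force_efms(model: MetabolicModel) -> set:
    """All support-minimal sign-feasible steady-state vectors, by brute force.

    Enumerates every reaction subset, keeps those whose stoichiometric
    submatrix has a one-dimensional rational nullspace spanned by a vector
    that is nonzero on the whole subset and sign-feasible (irreversible
    reactions run forward; a fully reversible vector is canonicalized so its
    first coefficient is positive), then discards supports that strictly
    contain another surviving support.
    """
    S, rows, cols = model.stoichiometric_matrix()
    M = sympy.Matrix([[sympy.Rational(x) for x in row] for row in S.tolist()])
    n = len(cols)
    rev = [model.reactions[r].reversible for r in cols]

    candidates: List[Tuple[frozenset, Tuple[Fraction, ...]]] = []
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            sub = M[:, list(combo)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            vec = null[0]
            if any(vec[k] == 0 for k in range(size)):
                continue  # true support is smaller; handled by its own subset
            full = [Fraction(0)] * n
            for k, j in enumerate(combo):
                full[j] = Fraction(int(vec[k].p), int(vec[k].q))
            for cand in (full, [-x for x in full]):
                if all(cand[j] >= 0 for j in range(n) if not rev[j]):
                    if all(rev[j] for j in combo) and cand[combo[0]] < 0:
                        continue
                    candidates.append((frozenset(combo), _normalize_int(tuple(cand))))

    minimal = set()
    supports = [s for s, _ in candidates]
    for supp, vec in candidates:
        if any(other < supp for other in supports):
            continue
        minimal.add(vec)
    return minimal


def efms_as_vectors(model: MetabolicModel, modes) -> set:
    cols = model.reaction_ids
    return {
        tuple(mode.coefficients.get(r, Fraction(0)) for r in cols) for mode in modes
    }
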