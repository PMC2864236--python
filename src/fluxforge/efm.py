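"""Elementary flux mode (EFM) enumeration and net-conversion analysis.

An EFM is a steady-state flux vector that respects irreversibility and has
support-minimal structure: no other admissible vector uses a proper subset
of its reactions.  EFMs are the indivisible pathway units of a network --
every admissible flux distribution is a non-negative combination of them.

Enumeration runs entirely in exact rational arithmetic (fractions.Fraction),
iterating the double-description step over the metabolite balance rows:
reversible reactions are split into forward/backward halves, rays are
combined pairwise to annihilate one balance at a time, non-minimal supports
are pruned, and the surviving rays are verified with the rank-based
elementarity test rank(S[:, support]) == |support| - 1.  Futile two-cycles
(forward plus backward half of one split reaction) are discarded.  Mode
coefficients are scaled to coprime integers.

Net conversions -- the overall external-metabolite balance of each mode --
are reduced by their greatest common divisor for readability, and identical
conversions are merged while remembering which modes produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Dict, List, Optional, Sequence, Set, Tuple

import sympy

from . import config
from .model import MetabolicModel, ModelError

#: enumeration refuses models larger than this (reduce first)
DEFAULT_MAX_REACTIONS = 64


@dataclass(frozen=True)
class ElementaryMode:
    """One elementary mode, with coprime-integer coefficients."""

    coefficients: Dict[str, Fraction] = field(hash=False)
    support: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "support", frozenset(r for r, c in self.coefficients.items() if c != 0)
        )

    def key(self) -> tuple:
        return tuple(sorted((r, c) for r, c in self.coefficients.items() if c != 0))


@dataclass(frozen=True)
class NetConversion:
    """GCD-normalized external balance shared by one or more modes."""

    balance: Dict[str, int] = field(hash=False)
    source_modes: frozenset = frozenset()

    def equation(self) -> str:
        lhs = [(m, -c) for m, c in sorted(self.balance.items()) if c < 0]
        rhs = [(m, c) for m, c in sorted(self.balance.items()) if c > 0]

        def side(terms):
            return " + ".join(f"{c} {m}" if c != 1 else m for m, c in terms) or "0"

        return f"{side(lhs)} -> {side(rhs)}"


def _rationalize(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**9)


def _normalize_int(vec: Sequence[Fraction]) -> Tuple[Fraction, ...]:
    """Scale a rational vector to coprime integers, keeping its sign."""
    denoms = [c.denominator for c in vec if c != 0]
    if not denoms:
        return tuple(vec)
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [c * lcm for c in vec]
    g = 0
    for c in ints:
        g = gcd(g, int(c))
    return tuple(c / g for c in ints) if g > 1 else tuple(ints)


def _rational_matrix(model: MetabolicModel):
    S, rows, cols = model.stoichiometric_matrix()
    Sf = [[_rationalize(x) for x in row] for row in S.tolist()]
    return Sf, rows, cols


def _support_minimal_prune(rays: List[Tuple[Tuple[Fraction, ...], frozenset]]):
    """Drop rays whose support strictly contains another ray's support; dedupe."""
    keep = []
    seen: Set[frozenset] = set()
    for vec, supp in rays:
        if supp in seen:
            continue
        if any(other < supp for _, other in rays):
            continue
        seen.add(supp)
        keep.append((vec, supp))
    return keep


def compute_efms(
    model: MetabolicModel, max_reactions: int = DEFAULT_MAX_REACTIONS
) -> List[ElementaryMode]:
    """Enumerate the complete set of elementary modes of ``model``.

    Returns modes ordered lexicographically by support for deterministic
    output.  For modes whose reactions are all reversible, the sign is
    canonicalized so the first reaction in model order runs forward.

    Raises on models with more than ``max_reactions`` reactions; run
    :func:`fluxforge.simplification.reduce_model` first to shrink them.
    """
    if len(model.reactions) > max_reactions:
        raise ModelError(
            f"model has {len(model.reactions)} reactions, above the enumeration "
            f"limit {max_reactions}; apply reduce_model first"
        )
    Sf, rows, cols = _rational_matrix(model)
    n = len(cols)
    reversible = [model.reactions[r].reversible for r in cols]

    # split reversible reactions: columns are (reaction index, direction)
    split: List[Tuple[int, int]] = []
    for j in range(n):
        split.append((j, +1))
        if reversible[j]:
            split.append((j, -1))
    ns = len(split)

    def col(i_row: int, k: int) -> Fraction:
        j, sgn = split[k]
        return Sf[i_row][j] * sgn

    # double-description iteration over balance rows, starting from the
    # non-negative orthant's extreme rays (the unit vectors)
    rays: List[Tuple[Tuple[Fraction, ...], frozenset]] = []
    zero = Fraction(0)
    for k in range(ns):
        vec = tuple(Fraction(int(i == k)) for i in range(ns))
        rays.append((vec, frozenset({k})))

    for i_row in range(len(rows)):
        coeffs = [col(i_row, k) for k in range(ns)]
        vals = [sum(c * v for c, v in zip(coeffs, vec) if v != 0) for vec, _ in rays]
        keep = [(vec, supp) for (vec, supp), d in zip(rays, vals) if d == 0]
        pos = [(vec, supp, d) for (vec, supp), d in zip(rays, vals) if d > 0]
        neg = [(vec, supp, d) for (vec, supp), d in zip(rays, vals) if d < 0]
        for pv, ps, pd in pos:
            for nv, nsupp, nd in neg:
                vec = _normalize_int(
                    tuple(pd * b - nd * a for a, b in zip(pv, nv))
                )
                keep.append((vec, frozenset(k for k in range(ns) if vec[k] != 0)))
        rays = _support_minimal_prune(keep)

    # merge split halves back into signed coefficients
    modes: List[ElementaryMode] = []
    seen: Set[tuple] = set()
    S_sym = sympy.Matrix(Sf)
    for vec, _ in rays:
        merged = [zero] * n
        futile = False
        used = {}
        for k, v in enumerate(vec):
            if v == 0:
                continue
            j, sgn = split[k]
            if j in used:
                futile = True  # both halves of one reversible reaction
                break
            used[j] = True
            merged[j] = v * sgn
        if futile or not any(merged):
            continue
        support = frozenset(cols[j] for j in range(n) if merged[j] != 0)
        # canonical sign when the whole mode is reversible
        idx = [j for j in range(n) if merged[j] != 0]
        if all(reversible[j] for j in idx) and merged[idx[0]] < 0:
            merged = [-x for x in merged]
        # rank-based elementarity: support-minimal iff the support columns
        # have a one-dimensional nullspace
        sub = S_sym[:, idx]
        if sub.rank() != len(idx) - 1:
            continue
        coefs = dict(zip(cols, _normalize_int(tuple(merged))))
        mode = ElementaryMode(coefficients={r: c for r, c in coefs.items() if c != 0})
        if mode.key() in seen:
            continue
        seen.add(mode.key())
        modes.append(mode)

    modes.sort(key=lambda m: tuple(sorted(cols.index(r) for r in m.support)))
    return modes


def net_conversions_of(
    model: MetabolicModel, modes: Sequence[ElementaryMode]
) -> List[NetConversion]:
    """External balances of the modes, integer-scaled, GCD-reduced, deduped.

    Modes with identical balances are merged into one conversion whose
    ``source_modes`` records their indices in the input sequence.
    """
    ext = model.external_metabolite_ids
    by_balance: Dict[tuple, Set[int]] = {}
    balances: Dict[tuple, Dict[str, int]] = {}
    for i, mode in enumerate(modes):
        bal: Dict[str, Fraction] = {}
        for rid, coef in mode.coefficients.items():
            if coef == 0:
                continue
            for mid, s in model.reactions[rid].stoichiometry.items():
                if mid in model.metabolites and model.metabolites[mid].external:
                    bal[mid] = bal.get(mid, Fraction(0)) + _rationalize(float(s)) * coef
        bal = {m: c for m, c in bal.items() if c != 0}
        if not bal:
            key = ()
            balances[key] = {}
        else:
            mids = sorted(bal)
            ints = _normalize_int(tuple(bal[m] for m in mids))
            balances_int = {m: int(c) for m, c in zip(mids, ints)}
            key = tuple(sorted(balances_int.items()))
            balances[key] = balances_int
        by_balance.setdefault(key, set()).add(i)
    out = [
        NetConversion(balance=balances[key], source_modes=frozenset(ixs))
        for key, ixs in by_balance.items()
    ]
    out.sort(key=lambda c: tuple(sorted(c.balance.items())))
    return out


def query_conversions(
    conversions: Sequence[NetConversion],
    require: Optional[Set[str]] = None,
    exclude: Optional[Set[str]] = None,
    yield_pair: Optional[Tuple[str, str]] = None,
) -> List[NetConversion]:
    """Filter conversions by metabolite presence/absence and sort by yield.

    Keeps conversions containing every ``require`` id and none of the
    ``exclude`` ids.  With ``yield_pair = (input, output)`` the result is
    sorted by descending output/input coefficient ratio; conversions lacking
    either metabolite (including a zero input coefficient) sort last with
    yield 0.  Ids unknown to every conversion raise an error.
    """
    require = set(require or set())
    exclude = set(exclude or set())
    if require & exclude:
        raise ValueError("require and exclude sets overlap")
    known: Set[str] = set()
    for c in conversions:
        known |= set(c.balance)
    asked = require | exclude | (set(yield_pair) if yield_pair else set())
    unknown = asked - known
    if unknown:
        raise ModelError(f"unknown external metabolites {sorted(unknown)}")

    kept = [
        c
        for c in conversions
        if require <= set(c.balance) and not (exclude & set(c.balance))
    ]
    if yield_pair is None:
        return kept
    inp, outp = yield_pair

    def conv_yield(c: NetConversion) -> float:
        cin = abs(c.balance.get(inp, 0))
        cout = c.balance.get(outp, 0)
        return cout / cin if cin else 0.0

    return sorted(kept, key=conv_yield, reverse=True)
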