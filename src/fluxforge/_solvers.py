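"""Thin wrappers around the numerical backends (HiGHS LP/MILP, OSQP).

Everything above this layer talks in numpy arrays; status strings are
normalized to {"optimal", "infeasible", "unbounded", "failed"}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp


@dataclass
class SolveResult:
    status: str
    x: Optional[np.ndarray]
    objective: Optional[float]
    eq_duals: Optional[np.ndarray] = None  # marginals of the equality rows


_LP_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[np.ndarray],
    b_eq: Optional[np.ndarray],
    bounds: Sequence[Tuple[float, float]],
    maximize: bool = False,
) -> SolveResult:
    """Optimize c.x subject to A_eq.x = b_eq and box bounds."""
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, float),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(bounds),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "failed")
    if status != "optimal":
        return SolveResult(status=status, x=None, objective=None)
    duals = None
    if A_eq is not None and res.eqlin is not None:
        # marginals are d(min obj)/d(b); undo the sign flip for maximization
        duals = sign * np.asarray(res.eqlin.marginals, float)
    return SolveResult(status="optimal", x=res.x, objective=sign * res.fun, eq_duals=duals)


_MILP_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_milp(
    c: np.ndarray,
    constraints: Sequence[LinearConstraint],
    integrality: np.ndarray,
    bounds: Bounds,
    maximize: bool = False,
) -> SolveResult:
    sign = -1.0 if maximize else 1.0
    res = milp(
        c=sign * np.asarray(c, float),
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
    )
    status = _MILP_STATUS.get(res.status, "failed")
    if status != "optimal" or res.x is None:
        # scipy.milp reports infeasible via status 2; keep that distinction
        return SolveResult(status=status if status != "optimal" else "failed", x=None, objective=None)
    return SolveResult(status="optimal", x=res.x, objective=sign * res.fun)


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
) -> SolveResult:
    """Minimize 0.5 x'Px + q'x subject to A_eq.x = b_eq and box bounds.

    Solved with OSQP at tight tolerances plus solution polishing, which
    recovers the exact KKT solution on non-degenerate problems.
    """
    import osqp

    n = len(q)
    lbs = np.array([b[0] for b in bounds], float)
    ubs = np.array([b[1] for b in bounds], float)
    A = sp.vstack([sp.csc_matrix(A_eq), sp.eye(n, format="csc")], format="csc")
    l = np.concatenate([b_eq, lbs])
    u = np.concatenate([b_eq, ubs])
    prob = osqp.OSQP()
    prob.setup(
        sp.csc_matrix(P), np.asarray(q, float), A, l, u,
        eps_abs=1e-10, eps_rel=1e-10, max_iter=200000, polishing=True, verbose=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "infeasible" in status:
        return SolveResult(status="infeasible", x=None, objective=None)
    if "solved" not in status:
        return SolveResult(status="failed", x=None, objective=None)
    x = np.asarray(res.x, float)
    obj = 0.5 * x @ (P @ x) + q @ x
    return SolveResult(status="optimal", x=x, objective=float(obj))
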