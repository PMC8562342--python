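"""Thin linear-programming layer over scipy's HiGHS interface.

All flux-balance problems in this package reduce to

    optimize  c . v
    s.t.      S v = 0          (steady state)
              extra_A v <= extra_b   (optional, e.g. optimality fixing)
              lb <= v <= ub

Absolute-value objectives (parsimonious flux) are handled by variable
splitting in :mod:`vinoflux.pfba`, not here; this module stays a dumb LP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

#: Sentinel for "unbounded" flux, COBRA convention.
BIG_BOUND = 1000.0


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    objective: float | None
    x: np.ndarray | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "max",
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> LPResult:
    """Solve a bounded LP; `sense` is "max" or "min" of ``c . x``."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    bounds = list(zip(np.asarray(lb, dtype=float), np.asarray(ub, dtype=float)))
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        return LPResult("optimal", sign * res.fun, np.asarray(res.x))
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    return LPResult("error", None, None)
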