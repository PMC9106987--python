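"""Thin mixed-integer modeling layer over :func:`scipy.optimize.milp` (HiGHS).

All exact solves in the toolkit (facility location, multiset multicover,
duty rostering, vehicle routing) build their models through this helper so
solver options — notably a tight MIP gap, since oracle tests compare against
exhaustive enumeration — live in one place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

#: relative MIP gap; effectively "prove optimality" at test scales
DEFAULT_GAP = 1e-9

_STATUS = {
    0: "optimal",
    1: "iteration_or_time_limit",
    2: "infeasible",
    3: "unbounded",
    4: "other",
}


@dataclass
class Solution:
    status: str
    x: np.ndarray | None
    objective: float | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class Model:
    """Incrementally built MILP: columns then row constraints, then solve."""

    _lb: list = field(default_factory=list)
    _ub: list = field(default_factory=list)
    _integer: list = field(default_factory=list)
    _obj: list = field(default_factory=list)
    _rows: list = field(default_factory=list)  # (coefs dict, lo, hi)

    def add_var(self, lb=0.0, ub=math.inf, integer=False, obj=0.0) -> int:
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(1 if integer else 0)
        self._obj.append(obj)
        return len(self._lb) - 1

    def add_vars(self, n, **kw) -> list[int]:
        return [self.add_var(**kw) for _ in range(n)]

    def add_constr(self, coefs: dict[int, float], lo=-math.inf, hi=math.inf) -> None:
        self._rows.append((dict(coefs), lo, hi))

    def set_obj(self, index: int, coef: float) -> None:
        self._obj[index] = coef

    @property
    def n_vars(self) -> int:
        return len(self._lb)

    def solve(self, time_limit: float | None = None, gap: float = DEFAULT_GAP) -> Solution:
        n = self.n_vars
        c = np.asarray(self._obj, dtype=float)
        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            lo = np.empty(len(self._rows))
            hi = np.empty(len(self._rows))
            for r, (coefs, l, h) in enumerate(self._rows):
                lo[r], hi[r] = l, h
                for j, a in coefs.items():
                    ri.append(r)
                    ci.append(j)
                    data.append(a)
            A = sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), n))
            constraints = [LinearConstraint(A, lo, hi)]
        options = {"mip_rel_gap": gap, "mip_abs_gap": gap}
        if time_limit is not None:
            options["time_limit"] = time_limit
        with warnings.catch_warnings():
            # scipy does not list mip_abs_gap but forwards it to HiGHS, which does
            warnings.filterwarnings("ignore", message="Unrecognized options")
            res = milp(
                c=c,
                constraints=constraints,
                integrality=np.asarray(self._integer),
                bounds=Bounds(
                    np.asarray(self._lb, dtype=float), np.asarray(self._ub, dtype=float)
                ),
                options=options,
            )
        status = _STATUS.get(res.status, "other")
        if res.x is None:
            return Solution(status=status, x=None, objective=None)
        x = np.asarray(res.x, dtype=float)
        # snap integer variables, guarding against solver round-off
        mask = np.asarray(self._integer, dtype=bool)
        x[mask] = np.round(x[mask])
        return Solution(status=status, x=x, objective=float(c @ x))

    def value(self, sol: Solution, index: int) -> float:
        return float(sol.x[index])

    def ivalue(self, sol: Solution, index: int) -> int:
        return int(round(sol.x[index]))
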