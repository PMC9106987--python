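"""Roster optimization: idealized fair loads, exact duty-plan MIP, rolling horizon.

The idealized plan solves a simplified problem — coverage constraints only,
no dispersion and no rest — and serves purely as a load reference for the
fairness brackets of the real plan.  Its sorted-descending load vector is
lexicographically minimal: the heaviest annual burden is as small as
possible, then the second heaviest, and so on.  The default method computes
this exactly by a sequence of MIPs (minimize the top load level, then the
number of pharmacies at that level, then the next level, ...); a min-load
greedy is available as a fast heuristic for long horizons but does not
guarantee the lexicographic property when pharmacies share coverage.
"""

from __future__ import annotations

import math

import numpy as np

from careplan._milp import Model
from careplan.errors import InfeasibleError, InputError
from careplan.pharmshift.instance import DutyPlan, IdealizedLoads, PharmacyInstance


def _check_coverable(instance: PharmacyInstance, need: int) -> None:
    bad = [m for m in instance.municipality_ids if len(instance.cover[m]) < need]
    if bad:
        raise InfeasibleError(
            "municipalities without enough pharmacies in reach",
            report={"family": "coverage", "municipalities": bad},
        )


# --------------------------------------------------------------------------
# idealized lexicographically fair loads


def _greedy_loads(instance: PharmacyInstance) -> dict[str, int]:
    """Per day, give each uncovered municipality the least-loaded eligible
    pharmacy (ties by identifier).  Heuristic reference only."""
    need = instance.required_coverage
    load = {p: 0 for p in instance.pharmacy_ids}
    for _ in range(instance.horizon_days):
        open_today: set[str] = set()
        for m in instance.municipality_ids:
            eligible = instance.cover[m]
            while len(open_today & set(eligible)) < need:
                cands = [p for p in eligible if p not in open_today]
                if not cands:
                    raise InfeasibleError(
                        "municipality cannot reach enough pharmacies",
                        report={"family": "coverage", "municipalities": [m]},
                    )
                p = min(cands, key=lambda p: (load[p], p))
                open_today.add(p)
                load[p] += 1
    return load


def _lex_min_loads(instance: PharmacyInstance) -> dict[str, int]:
    """Exact lexicographic minimization of the sorted-descending load vector
    for the coverage-only problem.

    Alternates two MIPs per load level: minimize the number of pharmacies
    whose load reaches the level (cumulatively), then minimize the next lower
    level.  Cumulative count caps pin each finished level, so any optimum of
    the final solve realizes the lexicographically minimal sorted vector.
    """
    P = instance.pharmacy_ids
    T = instance.horizon_days
    need = instance.required_coverage

    # finished levels as (threshold t_i, cumulative count N_i of loads >= t_i)
    levels: list[tuple[int, int]] = []

    def base_model():
        mdl = Model()
        duty = {(p, d): mdl.add_var(ub=1, integer=True) for p in P for d in range(T)}
        for d in range(T):
            for m in instance.municipality_ids:
                mdl.add_constr({duty[p, d]: 1.0 for p in instance.cover[m]}, lo=need)
        loads = {}
        for p in P:
            v = mdl.add_var(integer=True, ub=T)
            coefs = {duty[p, d]: 1.0 for d in range(T)}
            coefs[v] = -1.0
            mdl.add_constr(coefs, lo=0, hi=0)
            loads[p] = v
        t1 = levels[0][0] if levels else T
        for p in P:
            mdl.add_constr({loads[p]: 1.0}, hi=t1)
        for i, (t_i, N_i) in enumerate(levels):
            below = levels[i + 1][0] if i + 1 < len(levels) else None
            if below is None:
                continue  # frontier handled by the caller
            b = {p: mdl.add_var(ub=1, integer=True) for p in P}
            for p in P:
                # load_p <= below, unless gated up to the global max t1
                mdl.add_constr({loads[p]: 1.0, b[p]: -(t1 - below)}, hi=below)
            mdl.add_constr({b[p]: 1.0 for p in P}, hi=N_i)
        return mdl, loads

    def frontier_cap(mdl, loads, cap: int):
        """Unaccounted loads (beyond the last cumulative budget) <= cap."""
        if not levels:
            for p in P:
                mdl.add_constr({loads[p]: 1.0}, hi=cap)
            return
        t1 = levels[0][0]
        b = {p: mdl.add_var(ub=1, integer=True) for p in P}
        for p in P:
            mdl.add_constr({loads[p]: 1.0, b[p]: -(t1 - cap)}, hi=cap)
        mdl.add_constr({b[p]: 1.0 for p in P}, hi=levels[-1][1])

    def solve(mdl):
        sol = mdl.solve()
        if not sol.optimal:
            raise InfeasibleError(
                f"idealized plan solver status {sol.status}", report={"status": sol.status}
            )
        return sol

    # top level: minimal possible maximum load
    mdl, loads = base_model()
    z = mdl.add_var(integer=True, ub=T, obj=1.0)
    for p in P:
        mdl.add_constr({loads[p]: 1.0, z: -1.0}, hi=0)
    sol = solve(mdl)
    t = mdl.ivalue(sol, z)

    final = (mdl, sol, loads)
    while t >= 1:
        # minimal cumulative count of loads >= t, respecting the budget of
        # the previous level (at most N_prev loads may exceed t)
        mdl, loads = base_model()
        t1 = levels[0][0] if levels else t
        if levels:
            frontier_cap(mdl, loads, t)
        a = {p: mdl.add_var(ub=1, integer=True, obj=1.0) for p in P}
        for p in P:
            mdl.add_constr({loads[p]: 1.0, a[p]: -(t1 - t + 1)}, hi=t - 1)
        sol = solve(mdl)
        n_cum = int(round(sol.objective))
        levels.append((t, n_cum))
        final = (mdl, sol, loads)
        if n_cum >= len(P):
            break
        # minimal next lower level among the unaccounted loads
        mdl, loads = base_model()
        z = mdl.add_var(integer=True, ub=t - 1, obj=1.0)
        t1 = levels[0][0]
        b = {p: mdl.add_var(ub=1, integer=True) for p in P}
        for p in P:
            mdl.add_constr({loads[p]: 1.0, b[p]: -float(t1), z: -1.0}, hi=0)
        mdl.add_constr({b[p]: 1.0 for p in P}, hi=n_cum)
        sol = solve(mdl)
        t_next = mdl.ivalue(sol, z)
        if t_next == 0:
            mdl, loads = base_model()
            frontier_cap(mdl, loads, 0)
            sol = solve(mdl)
            final = (mdl, sol, loads)
            break
        t = t_next

    mdl, sol, loads = final
    return {p: mdl.ivalue(sol, loads[p]) for p in P}


def idealized_fair_plan(instance: PharmacyInstance, method: str = "auto") -> IdealizedLoads:
    """Load reference of the simplified (coverage-only) problem.

    ``exact`` guarantees lexicographic minimality; ``greedy`` is the fast
    heuristic; ``auto`` uses exact up to moderate problem sizes.
    """
    _check_coverable(instance, instance.required_coverage)
    if method == "auto":
        method = (
            "exact"
            if len(instance.pharmacy_ids) * instance.horizon_days <= 1500
            else "greedy"
        )
    if method == "exact":
        return IdealizedLoads(load=_lex_min_loads(instance))
    elif method == "greedy":
        return IdealizedLoads(load=_greedy_loads(instance))
    raise InputError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# full duty-plan MIP


def fairness_bounds(
    instance: PharmacyInstance, fairness: IdealizedLoads
) -> dict[str, tuple[int, int]]:
    """Multiplicative brackets around the idealized loads."""
    delta = instance.fairness_slack
    out = {}
    for p in instance.pharmacy_ids:
        ref = fairness.load.get(p, 0)
        out[p] = (math.floor((1 - delta) * ref), math.ceil((1 + delta) * ref))
    return out


def _build_duty_model(
    instance: PharmacyInstance,
    days,
    fairness: IdealizedLoads | None,
    fixed: dict[tuple[str, int], int] | None = None,
    min_services: dict[str, int] | None = None,
    max_services: dict[str, int] | None = None,
    use_instance_bounds: bool = True,
):
    """Shared constraint matrix for full-horizon and windowed solves.

    ``use_instance_bounds=False`` drops the instance-level minimum-services
    bound (windowed solves spread it across the horizon themselves).
    """
    P = instance.pharmacy_ids
    mdl = Model()
    duty = {}
    for p in P:
        for d in days:
            if fixed and (p, d) in fixed:
                v = fixed[p, d]
                duty[p, d] = mdl.add_var(lb=v, ub=v, integer=True, obj=1.0)
            else:
                duty[p, d] = mdl.add_var(ub=1, integer=True, obj=1.0)
    need = instance.required_coverage
    for d in days:
        for m in instance.municipality_ids:
            mdl.add_constr({duty[p, d]: 1.0 for p in instance.cover[m]}, lo=need)
        for pair in instance.conflicts:
            p, q = sorted(pair)
            mdl.add_constr({duty[p, d]: 1.0, duty[q, d]: 1.0}, hi=1)
    r = instance.rest_days
    if r > 0:
        for p in P:
            for i, d in enumerate(days):
                for d2 in days[i + 1 :]:
                    if d2 - d <= r:
                        mdl.add_constr({duty[p, d]: 1.0, duty[p, d2]: 1.0}, hi=1)
                    else:
                        break
    lo_tot = {p: float(instance.min_annual_services) if use_instance_bounds else 0.0 for p in P}
    hi_tot: dict[str, float] = {p: math.inf for p in P}
    if fairness is not None:
        for p, (lo, hi) in fairness_bounds(instance, fairness).items():
            lo_tot[p] = max(lo_tot[p], lo)
            hi_tot[p] = min(hi_tot[p], hi)
    if min_services:
        for p, v in min_services.items():
            lo_tot[p] = max(lo_tot[p], v)
    if max_services:
        for p, v in max_services.items():
            hi_tot[p] = min(hi_tot[p], v)
    for p in P:
        coefs = {duty[p, d]: 1.0 for d in days}
        if lo_tot[p] > 0 or hi_tot[p] < math.inf:
            mdl.add_constr(coefs, lo=lo_tot[p] if lo_tot[p] > 0 else -math.inf, hi=hi_tot[p])
    return mdl, duty


def _diagnose_infeasibility(instance: PharmacyInstance) -> dict:
    report = instance.structural_report()
    if not report:
        report = {"family": "interaction", "detail": "constraint families jointly infeasible"}
    return report


def solve_duty_plan(
    instance: PharmacyInstance, fairness: IdealizedLoads | None = None
) -> DutyPlan:
    """Minimum total out-of-hours services satisfying all constraint families."""
    _check_coverable(instance, instance.required_coverage)
    days = list(range(instance.horizon_days))
    mdl, duty = _build_duty_model(instance, days, fairness)
    sol = mdl.solve()
    if not sol.optimal:
        raise InfeasibleError("duty plan infeasible", report=_diagnose_infeasibility(instance))
    P = instance.pharmacy_ids
    mat = np.zeros((len(P), instance.horizon_days), dtype=bool)
    for i, p in enumerate(P):
        for d in days:
            mat[i, d] = mdl.ivalue(sol, duty[p, d]) == 1
    return DutyPlan(pharmacy_ids=P, horizon_days=instance.horizon_days, duty=mat)


# --------------------------------------------------------------------------
# rolling horizon


def _capacity(days_left: int, r: int) -> int:
    """Max services one pharmacy can still perform in ``days_left`` days."""
    return math.ceil(days_left / (r + 1)) if days_left > 0 else 0


def rolling_horizon_solve(
    instance: PharmacyInstance,
    window_days: int = 28,
    overlap_days: int = 7,
    fairness: IdealizedLoads | None = None,
) -> DutyPlan:
    """Windowed decomposition: solve ``window_days`` at a time, commit the
    first ``window_days - overlap_days``, carry rest constraints and service
    counts across the boundary.  The committed plan satisfies every
    full-horizon constraint; the total may exceed the exact optimum (the gap
    is the price of tractability on long horizons).  A window that is
    infeasible with fairness brackets is retried without them before failing.
    """
    T = instance.horizon_days
    W, O = window_days, overlap_days
    if not (0 <= O < W <= T):
        raise InputError("need 0 <= overlap < window <= horizon")
    _check_coverable(instance, instance.required_coverage)
    P = instance.pharmacy_ids
    r = instance.rest_days
    committed = np.zeros((len(P), T), dtype=bool)
    done_through = 0
    fb = fairness_bounds(instance, fairness) if fairness is not None else None

    while done_through < T:
        start = done_through
        end = min(T, start + W)
        days = list(range(start, end))
        commit_until = T if end == T else min(T, start + (W - O))
        fixed: dict[tuple[str, int], int] = {}
        for i, p in enumerate(P):
            for d in range(max(0, start - r), start):
                if committed[i, d]:
                    for d2 in days:
                        if d2 - d <= r:
                            fixed[p, d2] = 0
        counts = {p: int(committed[i, :start].sum()) for i, p in enumerate(P)}
        remaining_after = T - end
        min_base: dict[str, int] = {}
        min_fair: dict[str, int] = {}
        max_fair: dict[str, int] = {}
        for p in P:
            base_need = instance.min_annual_services - counts[p] - _capacity(remaining_after, r)
            if base_need > 0:
                min_base[p] = base_need
            if fb is not None:
                lo, hi = fb[p]
                fair_need = max(instance.min_annual_services, lo) - counts[p] - _capacity(
                    remaining_after, r
                )
                if fair_need > 0:
                    min_fair[p] = fair_need
                max_fair[p] = max(0, hi - counts[p])
        attempts = [(min_fair, max_fair)] if fb is not None else []
        attempts.append((min_base, {}))
        solved = None
        for mn, mx in attempts:
            mdl, duty = _build_duty_model(
                instance, days, None, fixed=fixed, min_services=mn, max_services=mx,
                use_instance_bounds=False,
            )
            sol = mdl.solve()
            if sol.optimal:
                solved = (mdl, sol, duty)
                break
        if solved is None:
            raise InfeasibleError(
                f"rolling-horizon window starting day {start} infeasible",
                report=_diagnose_infeasibility(instance),
            )
        mdl, sol, duty = solved
        for i, p in enumerate(P):
            for d in range(start, commit_until):
                committed[i, d] = mdl.ivalue(sol, duty[p, d]) == 1
        done_through = commit_until

    return DutyPlan(pharmacy_ids=P, horizon_days=T, duty=committed)
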