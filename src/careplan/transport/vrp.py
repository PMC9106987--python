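"""Lexicographic vehicle routing with general time windows.

Patient pickups are soft windows: a pickup may start late (the delay) but
never early — vehicles wait at the pickup location until the requested time.
Driver shifts are hard windows.  The objective is lexicographic: first
minimize the maximum delay over all patients, then, with that value fixed,
the total delay.  Infectious patients ride only on covid or floater
vehicles; infectious stops incur a protective-clothing/disinfection service
add-on, and floaters pay a changeover when consecutive stops switch
infection category.

The MIP uses continuous start times with big-M sequencing: one assignment
binary per (request, compatible vehicle), one precedence binary per request
pair.  Start times encode the route order, so no subtour constraints are
needed.  Both stages are solved to proven optimality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from careplan._milp import Model
from careplan.errors import InfeasibleError, InputError
from careplan.geonet import SpeedProfile, shortest_time
from careplan.transport.types import Stop, TransportRequest, TransportSchedule, Vehicle


class TravelTimes:
    """Cached point-to-point travel seconds on the street network."""

    def __init__(self, net, profile: SpeedProfile, respect_restrictions: bool = False):
        self.net = net
        self.profile = profile
        self.respect = respect_restrictions
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b)
        if key not in self._cache:
            self._cache[key] = shortest_time(
                self.net, self.profile, a, b, respect_restrictions=self.respect
            ).duration_s
        return self._cache[key]


def service_duration(req: TransportRequest, veh: Vehicle, tau) -> float:
    """Pickup start through dropoff end: loading (+ covid add-on), driving,
    unloading."""
    addon = veh.covid_addon_s if req.infectious else 0.0
    return req.load_s + addon + tau(req.pickup, req.dropoff) + req.unload_s


def _changeover(veh: Vehicle, a: TransportRequest, b: TransportRequest) -> float:
    if veh.fleet == "floater" and a.infectious != b.infectious:
        return veh.changeover_s
    return 0.0


def _servable_by(req, veh, tau, start_node, avail) -> bool:
    if not veh.can_serve(req):
        return False
    first = tau(start_node, req.pickup)
    if not math.isfinite(first):
        return False
    start = max(req.requested_s, avail + first)
    end = start + service_duration(req, veh, tau) + tau(req.dropoff, veh.depot)
    return math.isfinite(end) and end <= veh.shift_end_s


def solve_vrpgtw(
    requests,
    vehicles,
    net=None,
    profile: SpeedProfile | None = None,
    anchors: dict[str, tuple[str, float]] | None = None,
    tau: TravelTimes | None = None,
) -> TransportSchedule:
    """Two-stage lexicographic VRPGTW solve (min max delay, then total).

    ``anchors`` override a vehicle's initial position and availability time
    (used by online re-optimization); by default vehicles start at their
    depot when the shift opens.  Every route ends at the vehicle's depot by
    shift end.
    """
    requests = list(requests)
    vehicles = list(vehicles)
    if not vehicles:
        raise InputError("at least one vehicle required")
    if tau is None:
        if net is None or profile is None:
            raise InputError("either tau or (net, profile) must be given")
        tau = TravelTimes(net, profile)
    anchors = anchors or {}
    if not requests:
        return TransportSchedule(
            routes={v.id: [] for v in vehicles}, delays={}, d_max=0.0, total_delay=0.0
        )

    start_of, avail_of = {}, {}
    for v in vehicles:
        node, avail = anchors.get(v.id, (v.depot, v.shift_start_s))
        start_of[v.id] = node
        avail_of[v.id] = max(avail, v.shift_start_s)

    compat = {
        (i, v.id): True
        for i, r in enumerate(requests)
        for v in vehicles
        if _servable_by(r, v, tau, start_of[v.id], avail_of[v.id])
    }
    bad = [
        r.id
        for i, r in enumerate(requests)
        if not any((i, v.id) in compat for v in vehicles)
    ]
    if bad:
        raise InfeasibleError("requests unservable by any vehicle", report={"requests": bad})

    horizon = max(v.shift_end_s for v in vehicles)
    max_link = 0.0
    for i, a in enumerate(requests):
        for v in vehicles:
            max_link = max(max_link, service_duration(a, v, tau) + v.changeover_s)
        for b in requests:
            t = tau(a.dropoff, b.pickup)
            if math.isfinite(t):
                max_link = max(max_link, t)
    M = horizon + 2 * max_link + 1.0

    n = len(requests)

    def build(d_max_cap: float | None, minimize_total: bool):
        mdl = Model()
        x = {key: mdl.add_var(ub=1, integer=True) for key in compat}
        S = {i: mdl.add_var(lb=requests[i].requested_s, ub=horizon) for i in range(n)}
        delay = {i: mdl.add_var(obj=1.0 if minimize_total else 0.0) for i in range(n)}
        dmax = mdl.add_var(obj=0.0 if minimize_total else 1.0)
        if d_max_cap is not None:
            mdl.add_constr({dmax: 1.0}, hi=d_max_cap)
        for i, r in enumerate(requests):
            mdl.add_constr(
                {x[i, v.id]: 1.0 for v in vehicles if (i, v.id) in x}, lo=1, hi=1
            )
            # delay_i = S_i - requested_i (S_i >= requested_i by variable bound)
            mdl.add_constr({delay[i]: 1.0, S[i]: -1.0}, lo=-r.requested_s, hi=-r.requested_s)
            mdl.add_constr({dmax: 1.0, delay[i]: -1.0}, lo=0)
        for i, r in enumerate(requests):
            for v in vehicles:
                if (i, v.id) not in x:
                    continue
                lo0 = avail_of[v.id] + tau(start_of[v.id], r.pickup)
                # S_i >= lo0 - M(1 - x):  S_i - M x >= lo0 - M
                mdl.add_constr({S[i]: 1.0, x[i, v.id]: -M}, lo=lo0 - M)
                # S_i + dur + back <= shift_end + M(1 - x):  S_i + M x <= end - dur - back + M
                dur = service_duration(r, v, tau)
                back = tau(r.dropoff, v.depot)
                mdl.add_constr(
                    {S[i]: 1.0, x[i, v.id]: M}, hi=v.shift_end_s - dur - back + M
                )
        order = {}
        for i in range(n):
            for j in range(i + 1, n):
                order[i, j] = mdl.add_var(ub=1, integer=True)  # 1 <=> i before j
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                a, b = requests[i], requests[j]
                for v in vehicles:
                    if (i, v.id) not in x or (j, v.id) not in x:
                        continue
                    link = (
                        service_duration(a, v, tau)
                        + tau(a.dropoff, b.pickup)
                        + _changeover(v, a, b)
                    )
                    if not math.isfinite(link):
                        link = M  # unreachable leg: order effectively forbidden
                    # S_j - S_i >= link when (i before j) and both on v
                    coefs = {S[j]: 1.0, S[i]: -1.0, x[i, v.id]: -M, x[j, v.id]: -M}
                    if i < j:
                        coefs[order[i, j]] = -M  # active when order = 1
                        lo = link - 3 * M
                    else:
                        coefs[order[j, i]] = M  # active when order = 0
                        lo = link - 2 * M
                    mdl.add_constr(coefs, lo=lo)
        return mdl, x, S, delay, dmax

    # stage 1: minimize the maximum delay
    mdl, x, S, delay, dmax = build(None, minimize_total=False)
    sol = mdl.solve()
    if not sol.optimal:
        raise InfeasibleError(
            "no feasible schedule within shifts", report={"status": sol.status}
        )
    d_star = sol.x[dmax]
    # stage 2: fix it (tiny slack for solver round-off), minimize total delay
    mdl, x, S, delay, dmax = build(d_star + 1e-7 + 1e-9 * d_star, minimize_total=True)
    sol = mdl.solve()
    if not sol.optimal:  # numerically impossible, but fail loudly
        raise InfeasibleError("stage-2 solve failed", report={"status": sol.status})

    routes: dict[str, list[Stop]] = {v.id: [] for v in vehicles}
    delays: dict[str, float] = {}
    veh_by_id = {v.id: v for v in vehicles}
    for i, r in enumerate(requests):
        vid = next(v.id for v in vehicles if (i, v.id) in x and mdl.ivalue(sol, x[i, v.id]) == 1)
        start = float(sol.x[S[i]])
        dur = service_duration(r, veh_by_id[vid], tau)
        routes[vid].append(Stop(request_id=r.id, pickup_start_s=start, dropoff_end_s=start + dur))
        delays[r.id] = max(0.0, start - r.requested_s)
    for vid in routes:
        routes[vid].sort(key=lambda s: (s.pickup_start_s, s.request_id))
    sched = TransportSchedule(
        routes=routes,
        delays=delays,
        d_max=max(delays.values(), default=0.0),
        total_delay=sum(delays.values()),
    )
    return sched


# --------------------------------------------------------------------------
# metrics


@dataclass
class GanttRow:
    vehicle: str
    request: str
    start_s: float
    end_s: float
    category: str  # 'covid' | 'clean'


@dataclass
class ScheduleMetrics:
    d_max: float
    total_delay: float
    busy_fraction: dict[str, float]
    shift_violations: int
    gantt: list[GanttRow]


def schedule_metrics(
    schedule: TransportSchedule,
    vehicles=None,
    requests=None,
    exclude: set[str] | None = None,
) -> ScheduleMetrics:
    """Deterministic recomputation from stop times.  ``exclude`` drops
    request ids (e.g. unmaterialized dummies) from the delay statistics."""
    exclude = exclude or set()
    req_by_id = {r.id: r for r in (requests or [])}
    veh_by_id = {v.id: v for v in (vehicles or [])}
    delays = {rid: d for rid, d in schedule.delays.items() if rid not in exclude}
    gantt = []
    busy = {}
    violations = 0
    for vid, stops in sorted(schedule.routes.items()):
        busy_time = 0.0
        for s in stops:
            cat = "clean"
            r = req_by_id.get(s.request_id)
            if r is not None and r.infectious:
                cat = "covid"
            gantt.append(GanttRow(vid, s.request_id, s.pickup_start_s, s.dropoff_end_s, cat))
            busy_time += s.dropoff_end_s - s.pickup_start_s
            v = veh_by_id.get(vid)
            if v is not None and s.dropoff_end_s > v.shift_end_s + 1e-9:
                violations += 1
        v = veh_by_id.get(vid)
        span = (v.shift_end_s - v.shift_start_s) if v is not None else None
        busy[vid] = busy_time / span if span else 0.0
    return ScheduleMetrics(
        d_max=max(delays.values(), default=0.0),
        total_delay=sum(delays.values()),
        busy_fraction=busy,
        shift_violations=violations,
        gantt=gantt,
    )
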