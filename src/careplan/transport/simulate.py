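"""Deterministic replay of one transport day under a dispatch policy.

``reoptimize``: the plannable requests are solved once at day start; every
ad-hoc arrival triggers a full re-solve with started/finished transports
fixed and vehicles anchored at their current positions.  ``nearest_available``
is the status-quo baseline: when a transport is due, send the nearest
available compatible vehicle, queueing FIFO when none is free.  Travel is
deterministic, so realized times equal the (final) planned times.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

from careplan.errors import InputError
from careplan.transport.online import make_dummy_returns, match_dummy, reoptimize
from careplan.transport.types import DayState, Stop, TransportRequest, TransportSchedule
from careplan.transport.vrp import TravelTimes, service_duration, solve_vrpgtw


@dataclass
class DayResult:
    schedule: TransportSchedule
    delays: dict[str, float]  # realized, real requests only (dummies excluded)
    d_max: float
    total_delay: float
    unserved: tuple[str, ...]
    requests: dict[str, TransportRequest] = field(default_factory=dict)


def _realized(schedule: TransportSchedule, req_map, unserved) -> DayResult:
    delays = {}
    for vid, stops in schedule.routes.items():
        for s in stops:
            r = req_map.get(s.request_id)
            if r is None or r.dummy:
                continue
            delays[r.id] = max(0.0, s.pickup_start_s - r.requested_s)
    return DayResult(
        schedule=schedule,
        delays=delays,
        d_max=max(delays.values(), default=0.0),
        total_delay=sum(delays.values()),
        unserved=tuple(unserved),
        requests=dict(req_map),
    )


def _simulate_reoptimize(day, vehicles, tau, dummy_rule) -> DayResult:
    req_map: dict[str, TransportRequest] = {r.id: r for r in day.plannable}
    initial = list(day.plannable)
    if dummy_rule is not None:
        for d in make_dummy_returns(day.plannable, dummy_rule):
            req_map[d.id] = d
            initial.append(d)
    schedule = solve_vrpgtw(initial, vehicles, tau=tau)
    unserved: list[str] = []

    for adhoc in sorted(day.adhoc, key=lambda r: (r.release_s, r.id)):
        now = adhoc.release_s
        executed: dict[str, list[Stop]] = {}
        positions: dict[str, tuple[str, float]] = {}
        outstanding: list[TransportRequest] = []
        for v in vehicles:
            stops = schedule.routes.get(v.id, [])
            done = [s for s in stops if s.pickup_start_s <= now]
            rest = [s for s in stops if s.pickup_start_s > now]
            executed[v.id] = done
            if done:
                last = done[-1]
                positions[v.id] = (req_map[last.request_id].dropoff, last.dropoff_end_s)
            else:
                positions[v.id] = (v.depot, v.shift_start_s)
            outstanding.extend(req_map[s.request_id] for s in rest)
        # materialization: an actual return replaces its dummy placeholder
        dummy = match_dummy(outstanding, adhoc)
        if dummy is not None:
            outstanding = [r for r in outstanding if r.id != dummy.id]
            del req_map[dummy.id]
        req_map[adhoc.id] = adhoc
        state = DayState(now_s=now, executed=executed, positions=positions, outstanding=outstanding)
        schedule = reoptimize(state, [adhoc], vehicles, tau=tau)
        unserved.extend(schedule.unserved)
    return _realized(schedule, req_map, unserved)


def _simulate_nearest(day, vehicles, tau) -> DayResult:
    req_map = {r.id: r for r in day.plannable}
    for r in day.adhoc:
        req_map[r.id] = r
    veh_state = {
        v.id: {"node": v.depot, "free_at": v.shift_start_s, "busy": False, "last_cat": None}
        for v in vehicles
    }
    veh_by_id = {v.id: v for v in vehicles}
    routes: dict[str, list[Stop]] = {v.id: [] for v in vehicles}
    unserved: list[str] = []
    queue: list[TransportRequest] = []

    heap = []
    seq = 0
    for r in sorted(req_map.values(), key=lambda r: r.id):
        heapq.heappush(heap, (max(r.requested_s, r.release_s), 0, seq, "due", r.id))
        seq += 1
    for v in vehicles:
        heapq.heappush(heap, (v.shift_start_s, 1, seq, "wake", v.id))
        seq += 1

    def try_dispatch(r: TransportRequest, now: float) -> bool:
        cands = []
        for v in vehicles:
            st = veh_state[v.id]
            if st["busy"] or not v.can_serve(r) or now < v.shift_start_s:
                continue
            trav = tau(st["node"], r.pickup)
            if not math.isfinite(trav):
                continue
            if v.fleet == "floater" and st["last_cat"] is not None and (
                st["last_cat"] != ("covid" if r.infectious else "clean")
            ):
                trav += v.changeover_s
            cands.append((trav, st["free_at"], v.id))
        if not cands:
            return False
        trav, _, vid = min(cands)
        v = veh_by_id[vid]
        st = veh_state[vid]
        start = max(now + trav, r.requested_s)
        end = start + service_duration(r, v, tau)
        routes[vid].append(Stop(request_id=r.id, pickup_start_s=start, dropoff_end_s=end))
        st.update(
            busy=True,
            node=r.dropoff,
            free_at=end,
            last_cat="covid" if r.infectious else "clean",
        )
        nonlocal seq
        heapq.heappush(heap, (end, 2, seq, "free", vid))
        seq += 1
        return True

    while heap:
        now, _, _, kind, payload = heapq.heappop(heap)
        if kind == "due":
            r = req_map[payload]
            if not any(v.can_serve(r) for v in vehicles):
                unserved.append(r.id)
                continue
            if not try_dispatch(r, now):
                queue.append(r)
        elif kind == "free":
            veh_state[payload]["busy"] = False
            for r in list(queue):
                if try_dispatch(r, now):
                    queue.remove(r)
                    break
        else:  # wake: a shift began; drain what we can
            for r in list(queue):
                if try_dispatch(r, now):
                    queue.remove(r)
    unserved.extend(r.id for r in queue)
    delays = {}
    schedule = TransportSchedule(routes=routes, delays={}, unserved=tuple(unserved))
    for vid, stops in routes.items():
        for s in stops:
            schedule.delays[s.request_id] = max(
                0.0, s.pickup_start_s - req_map[s.request_id].requested_s
            )
    schedule.d_max = max(schedule.delays.values(), default=0.0)
    schedule.total_delay = sum(schedule.delays.values())
    return _realized(schedule, req_map, unserved)


def simulate_transport_day(
    day,
    vehicles,
    net=None,
    profile=None,
    policy: str = "reoptimize",
    dummy_rule=None,
    tau: TravelTimes | None = None,
) -> DayResult:
    """Replay one day under ``reoptimize`` or ``nearest_available``.

    ``dummy_rule`` (reoptimize only) maps a dialysis request to an estimated
    stay in seconds; dummy returns are planned from day start and replaced on
    materialization.
    """
    if tau is None:
        if net is None or profile is None:
            raise InputError("either tau or (net, profile) must be given")
        tau = TravelTimes(net, profile)
    if policy == "reoptimize":
        return _simulate_reoptimize(day, vehicles, tau, dummy_rule)
    elif policy == "nearest_available":
        return _simulate_nearest(day, vehicles, tau)
    raise InputError(f"unknown policy {policy!r}")


def routes_to_geojson(schedule: TransportSchedule, requests, net) -> dict:
    """Route map export: one LineString per vehicle through its stop nodes
    plus typed stop markers (depot handling left to the caller)."""
    req_by_id = {r.id: r for r in requests}
    features = []
    for vid, stops in sorted(schedule.routes.items()):
        coords = []
        for s in stops:
            r = req_by_id.get(s.request_id)
            if r is None:
                continue
            for node, kind, t in (
                (r.pickup, "pickup", s.pickup_start_s),
                (r.dropoff, "dropoff", s.dropoff_end_s),
            ):
                if node in net.nodes:
                    coords.append(list(net.nodes[node]))
                    features.append(
                        {
                            "type": "Feature",
                            "geometry": {"type": "Point", "coordinates": list(net.nodes[node])},
                            "properties": {
                                "vehicle": vid,
                                "request": s.request_id,
                                "type": kind,
                                "time_s": t,
                                "delay_s": schedule.delays.get(s.request_id, 0.0),
                            },
                        }
                    )
        if len(coords) >= 2:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": coords},
                    "properties": {"vehicle": vid},
                }
            )
    return {"type": "FeatureCollection", "features": features}
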