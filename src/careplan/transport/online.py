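"""Online re-optimization and dummy return transports.

When an ad-hoc request arrives mid-day the whole problem is re-solved:
started or finished transports are fixed, vehicles are anchored at their
current positions and availability times, and everything outstanding may be
rescheduled.  Dialysis outward trips spawn *dummy* return transports (origin
and destination swapped, time estimated from the expected stay); when the
actual return materializes the dummy is replaced and the schedule re-solved.
"""

from __future__ import annotations

from dataclasses import replace

from careplan.errors import InfeasibleError
from careplan.transport.types import DayState, Stop, TransportRequest, TransportSchedule
from careplan.transport.vrp import TravelTimes, solve_vrpgtw


def reoptimize(
    state: DayState,
    new_requests,
    vehicles,
    net=None,
    profile=None,
    tau: TravelTimes | None = None,
) -> TransportSchedule:
    """Re-solve outstanding + new requests around the executed prefix.

    Executed stops are returned byte-identical.  A new request that cannot be
    fit is flagged in ``unserved`` and the remaining schedule returned.
    """
    state.validate()
    anchors = {vid: pos for vid, pos in state.positions.items()}
    requests = list(state.outstanding) + list(new_requests)
    new_ids = {r.id for r in new_requests}
    unserved: list[str] = []
    while True:
        try:
            sched = solve_vrpgtw(
                requests, vehicles, net=net, profile=profile, anchors=anchors, tau=tau
            )
            break
        except InfeasibleError as e:
            drop = [rid for rid in e.report.get("requests", []) if rid in new_ids]
            if not drop:
                raise
            unserved.extend(drop)
            requests = [r for r in requests if r.id not in drop]
    routes = {}
    for vid in sorted({*state.executed, *sched.routes}):
        routes[vid] = [replace(s, executed=True) for s in state.executed.get(vid, [])] + list(
            sched.routes.get(vid, [])
        )
    return TransportSchedule(
        routes=routes,
        delays=sched.delays,
        d_max=sched.d_max,
        total_delay=sched.total_delay,
        unserved=tuple(unserved),
    )


def make_dummy_returns(requests, stay_estimate) -> list[TransportRequest]:
    """Dummy return trip per dialysis request: destination back to origin at
    the outward requested time plus the estimated stay."""
    out = []
    for r in requests:
        if not r.dialysis or r.dummy:
            continue
        stay = float(stay_estimate(r))
        out.append(
            TransportRequest(
                id=f"{r.id}:return",
                pickup=r.dropoff,
                dropoff=r.pickup,
                requested_s=r.requested_s + stay,
                load_s=r.load_s,
                unload_s=r.unload_s,
                infectious=r.infectious,
                dialysis=False,
                release_s=r.release_s,
                dummy=True,
            )
        )
    return out


def match_dummy(outstanding, actual: TransportRequest) -> TransportRequest | None:
    """The dummy an actual (materialized) return replaces: same origin and
    destination, first by identifier."""
    cands = [
        d
        for d in outstanding
        if d.dummy and d.pickup == actual.pickup and d.dropoff == actual.dropoff
    ]
    return min(cands, key=lambda d: d.id) if cands else None
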