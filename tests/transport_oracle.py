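"""Brute-force oracle for the lexicographic VRPGTW on tiny instances.

Enumerates every assignment of requests to compatible vehicles and every
service order per vehicle; for a fixed sequence the earliest feasible start
times are delay-optimal (delays are one-sided in start times), so the
best (max delay, total delay) over the enumeration is the lexicographic
optimum.  Travel times must be metric (they come from shortest paths).
"""

import itertools
import math

from careplan.transport.vrp import _changeover, service_duration


class EuclidTau:
    """Metric travel times: Euclidean distance between named points / speed."""

    def __init__(self, points: dict[str, tuple[float, float]], speed_ms: float = 10.0):
        self.points = points
        self.speed = speed_ms

    def __call__(self, a: str, b: str) -> float:
        (x1, y1), (x2, y2) = self.points[a], self.points[b]
        return math.hypot(x1 - x2, y1 - y2) / self.speed


def evaluate_sequence(seq, veh, tau, anchor=None):
    """(list of start times, feasible?) for a fixed sequence on one vehicle."""
    node, avail = anchor if anchor else (veh.depot, veh.shift_start_s)
    cur_node, cur_time = node, max(avail, veh.shift_start_s)
    starts = []
    prev = None
    for r in seq:
        trav = tau(cur_node, r.pickup)
        cho = _changeover(veh, prev, r) if prev is not None else 0.0
        start = max(cur_time + trav + cho, r.requested_s)
        dur = service_duration(r, veh, tau)
        if start + dur + tau(r.dropoff, veh.depot) > veh.shift_end_s + 1e-9:
            return None
        starts.append(start)
        cur_time = start + dur
        cur_node = r.dropoff
        prev = r
    return starts


def brute_force_vrpgtw(requests, vehicles, tau, anchors=None):
    """Lexicographic optimum (d_max, total) or None when infeasible."""
    anchors = anchors or {}
    best = None
    vids = [v.id for v in vehicles]
    for assign in itertools.product(range(len(vehicles)), repeat=len(requests)):
        groups = {k: [] for k in range(len(vehicles))}
        ok = True
        for i, k in enumerate(assign):
            if not vehicles[k].can_serve(requests[i]):
                ok = False
                break
            groups[k].append(requests[i])
        if not ok:
            continue
        for perms in itertools.product(
            *(itertools.permutations(groups[k]) for k in range(len(vehicles)))
        ):
            delays = []
            feasible = True
            for k, seq in enumerate(perms):
                veh = vehicles[k]
                starts = evaluate_sequence(seq, veh, tau, anchors.get(veh.id))
                if starts is None:
                    feasible = False
                    break
                delays.extend(s - r.requested_s for s, r in zip(starts, seq))
            if not feasible:
                continue
            cand = (max(delays, default=0.0), sum(delays))
            if best is None or cand < best:
                best = cand
    return best
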