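"""Event-based simulation of emergency-doctor operations.

Doctors idle at their stations or drive back after a mission; while returning
they remain dispatchable from their current position along the return path
(approximated by finishing the current street segment, then re-routing).  On
an alarm the nearest available doctor (by estimated travel time) is sent; if
none is available the emergency queues FIFO.  Response time is measured from
alarm to arrival at the scene.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from careplan.errors import InputError
from careplan.emsplan.cover import Allocation
from careplan.geonet import SpeedProfile, shortest_time
from careplan.synthgeo import EmergencyLog, SyntheticRegion


@dataclass(frozen=True)
class EmsEvent:
    emergency_index: int
    alarm_s: float
    dispatch_s: float
    doctor_id: str
    arrival_s: float
    response_s: float  # arrival - alarm
    wait_queue_s: float  # dispatch - alarm
    scene: str


@dataclass
class EmsEventLog:
    events: tuple[EmsEvent, ...]

    def __post_init__(self):
        for e in self.events:
            if not (e.arrival_s >= e.dispatch_s >= e.alarm_s):
                raise InputError("event times must satisfy arrival >= dispatch >= alarm")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.events])


class _Router:
    """Cached shortest-time queries on the region's network."""

    def __init__(self, net, profile: SpeedProfile, respect_restrictions: bool = False):
        self.net = net
        self.profile = profile
        self.respect = respect_restrictions
        self._cache: dict[tuple[str, str], tuple[float, tuple[str, ...] | None]] = {}

    def query(self, a: str, b: str) -> tuple[float, tuple[str, ...] | None]:
        key = (a, b)
        if key not in self._cache:
            res = shortest_time(
                self.net, self.profile, a, b, respect_restrictions=self.respect
            )
            self._cache[key] = (res.duration_s, res.path)
        return self._cache[key]

    def time(self, a: str, b: str) -> float:
        return self.query(a, b)[0]

    def timed_path(self, a: str, b: str) -> list[tuple[str, float]]:
        """Return path as [(node reached, cumulative seconds), ...] from a."""
        dur, path = self.query(a, b)
        if path is None:
            return []
        node = a
        t = 0.0
        out = [(a, 0.0)]
        for eid in path:
            e = self.net.edges[eid]
            node = e.v if e.u == node else e.u
            t += self.profile.time_s(e.length_m, e.cls)
            out.append((node, t))
        return out


@dataclass
class _Doctor:
    id: str
    home: str
    state: str = "idle"  # idle | returning | busy
    node: str = ""  # current/last anchor node
    idle_since: float = 0.0
    busy_until: float = math.inf
    return_start: float = 0.0
    return_path: list = field(default_factory=list)  # [(node, cum_s), ...]

    def available(self) -> bool:
        return self.state in ("idle", "returning")

    def position_anchor(self, now: float) -> tuple[str, float]:
        """(node, seconds until the doctor stands at that node).

        Idle doctors are at their node now; returning doctors finish the
        street segment they are on, yielding its end node slightly later.
        """
        if self.state == "idle":
            return self.node, 0.0
        elapsed = now - self.return_start
        for node, cum in self.return_path:
            if cum >= elapsed - 1e-9:
                return node, cum - elapsed
        return self.home, 0.0


def simulate_ems(
    region: SyntheticRegion,
    stations,
    alloc: Allocation,
    log: EmergencyLog,
    profile: SpeedProfile,
    respect_restrictions: bool = False,
    hospital_handover_s: float = 0.0,
) -> EmsEventLog:
    """Replay an emergency log under a supplier allocation at stations."""
    stations = sorted(set(stations))
    for s in stations:
        if s not in region.network.nodes:
            raise InputError(f"station {s} not in network")
    total = sum(alloc.suppliers.get(s, 0) for s in stations)
    if total == 0 and log.records:
        raise InputError("no doctors allocated but emergency log is non-empty")

    router = _Router(region.network, profile, respect_restrictions)
    doctors = []
    for s in stations:
        for k in range(alloc.suppliers.get(s, 0)):
            doctors.append(_Doctor(id=f"{s}/{k}", home=s, node=s))

    # event heap: (time, priority, seq, kind, payload); frees before alarms
    heap = []
    seq = 0
    for idx, rec in enumerate(log.records):
        heapq.heappush(heap, (rec.time_s, 1, seq, "alarm", idx))
        seq += 1

    queue: list[tuple[float, int]] = []  # (alarm time, emergency index) FIFO
    events: dict[int, EmsEvent] = {}

    def refresh(doc: _Doctor, now: float):
        if doc.state == "returning":
            elapsed = now - doc.return_start
            if not doc.return_path or elapsed >= doc.return_path[-1][1] - 1e-9:
                doc.state = "idle"
                doc.node = doc.home
                doc.idle_since = doc.return_start + (
                    doc.return_path[-1][1] if doc.return_path else 0.0
                )

    def estimated_travel(doc: _Doctor, scene: str, now: float) -> float:
        anchor, lead = doc.position_anchor(now)
        t = router.time(anchor, scene)
        return lead + t if math.isfinite(t) else math.inf

    def dispatch(idx: int, now: float):
        rec = log.records[idx]
        cands = []
        for doc in doctors:
            refresh(doc, now)
            if not doc.available():
                continue
            trav = estimated_travel(doc, rec.node, now)
            if math.isfinite(trav):
                cands.append((trav, doc.idle_since, doc.id, doc))
        if not cands:
            queue.append((rec.time_s, idx))
            return
        trav, _, _, doc = min(cands, key=lambda c: (c[0], c[1], c[2]))
        arrival = now + trav
        end_node = rec.node
        busy_until = arrival + rec.duration_s
        if rec.transport and rec.hospital is not None:
            leg = router.time(rec.node, rec.hospital)
            if math.isfinite(leg):
                busy_until += leg + hospital_handover_s
                end_node = rec.hospital
        doc.state = "busy"
        doc.node = end_node
        doc.busy_until = busy_until
        events[idx] = EmsEvent(
            emergency_index=idx,
            alarm_s=rec.time_s,
            dispatch_s=now,
            doctor_id=doc.id,
            arrival_s=arrival,
            response_s=arrival - rec.time_s,
            wait_queue_s=now - rec.time_s,
            scene=rec.node,
        )
        nonlocal seq
        heapq.heappush(heap, (busy_until, 0, seq, "free", doc.id))
        seq += 1

    by_id = {d.id: d for d in doctors}
    while heap:
        now, _, _, kind, payload = heapq.heappop(heap)
        if kind == "alarm":
            dispatch(payload, now)
        else:  # free: service completed, start driving home; dispatchable
            doc = by_id[payload]
            doc.state = "returning"
            doc.busy_until = math.inf
            doc.return_start = now
            doc.return_path = router.timed_path(doc.node, doc.home)
            doc.idle_since = now
            if queue:
                _, idx = queue.pop(0)
                dispatch(idx, now)

    undispatched = [i for i in range(len(log.records)) if i not in events]
    if undispatched:
        raise InputError(f"emergencies never served (unreachable scenes): {undispatched}")
    ordered = tuple(events[i] for i in sorted(events))
    return EmsEventLog(events=ordered)


@dataclass
class ResponseSummary:
    per_municipality_median_s: dict[str, float | None]
    overall_median_s: float | None
    histogram_bin_edges_s: tuple[float, ...]
    histogram_counts: tuple[int, ...]


def response_time_summary(
    events: EmsEventLog, region: SyntheticRegion, bin_width_s: float = 120.0
) -> ResponseSummary:
    """Median response time per municipality plus an overall histogram.

    Municipalities without any emergency are reported as ``None`` (missing),
    never as zero.
    """
    responses = {m: [] for m in sorted(region.municipalities)}
    all_r = []
    for e in events.events:
        m = region.node_municipality.get(e.scene)
        if m is not None:
            responses[m].append(e.response_s)
        all_r.append(e.response_s)
    per_mun = {
        m: (float(np.median(v)) if v else None) for m, v in responses.items()
    }
    overall = float(np.median(all_r)) if all_r else None
    if all_r:
        top = max(all_r)
        edges = np.arange(0.0, top + bin_width_s, bin_width_s)
        if len(edges) < 2:
            edges = np.array([0.0, bin_width_s])
        counts, edges = np.histogram(all_r, bins=edges)
    else:
        edges, counts = np.array([0.0, bin_width_s]), np.array([], dtype=int)
    return ResponseSummary(
        per_municipality_median_s=per_mun,
        overall_median_s=overall,
        histogram_bin_edges_s=tuple(float(x) for x in edges),
        histogram_counts=tuple(int(c) for c in counts),
    )


def incidence_from_travel_time(
    region: SyntheticRegion,
    stations,
    profile: SpeedProfile,
    threshold_s: float = 720.0,
    respect_restrictions: bool = False,
) -> set[tuple[str, str]]:
    """Location incident to a municipality iff its center is reachable within
    the threshold (default 12 min) under the given (blue-light) profile."""
    inc = set()
    for s in sorted(set(stations)):
        for m, mu in region.municipalities.items():
            t = shortest_time(
                region.network, profile, s, mu.center_node,
                respect_restrictions=respect_restrictions,
            ).duration_s
            if t <= threshold_s:
                inc.add((s, m))
    return inc
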