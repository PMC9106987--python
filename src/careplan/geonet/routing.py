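"""Shortest travel times on street networks, with or without turn restrictions.

Two restriction-aware query modes are provided and must agree:

* ``state`` — a label-correcting Dijkstra over (recent-arc-history) states;
  efficient when the number of restrictions is small relative to the network.
* ``expanded`` — the maneuver-expanded graph built explicitly and solved with
  :mod:`networkx`; kept as an independent verification path.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import networkx as nx

from careplan.errors import ConfigurationError, InputError
from careplan.geonet.network import StreetNetwork

KMH_TO_MS = 1000.0 / 3600.0


@dataclass(frozen=True)
class SpeedProfile:
    """Average speed per street class for one vehicle type, km/h."""

    speeds: dict[str, float]
    vehicle_type: str = "car"

    def __post_init__(self):
        for cls, v in self.speeds.items():
            if not v >= 1.0:
                raise ConfigurationError(f"speed for class {cls!r} must be >= 1 km/h, got {v}")

    def time_s(self, length_m: float, cls: str) -> float:
        try:
            v = self.speeds[cls]
        except KeyError:
            raise ConfigurationError(f"speed profile has no entry for street class {cls!r}")
        return length_m / (v * KMH_TO_MS)


@dataclass(frozen=True)
class RouteResult:
    duration_s: float
    path: tuple[str, ...] | None  # edge ids; None when unreachable

    @property
    def reachable(self) -> bool:
        return self.path is not None


def _arc_weight(profile: SpeedProfile | None):
    """Arc weight: travel seconds under ``profile``; plain meters when None."""
    if profile is None:
        return lambda length, cls: length
    return profile.time_s


def _plain_dijkstra(net: StreetNetwork, weight, sources: dict[str, float], dest: str | None):
    """Node-level Dijkstra, ties broken by ascending node id for reproducible
    paths.  Returns (dist, parent_arc) maps; stops early at ``dest``."""
    adj = net.out_arcs()
    dist: dict[str, float] = {}
    parent: dict[str, tuple[str, str]] = {}  # node -> (edge id, predecessor node)
    heap = [(d0, s) for s, d0 in sorted(sources.items())]
    heapq.heapify(heap)
    pending = dict(sources)
    while heap:
        d, n = heapq.heappop(heap)
        if n in dist or d > pending.get(n, math.inf):
            continue
        dist[n] = d
        if n == dest:
            break
        for eid, head, length, cls in adj[n]:
            nd = d + weight(length, cls)
            if nd < pending.get(head, math.inf) - 1e-15:
                pending[head] = nd
                parent[head] = (eid, n)
                heapq.heappush(heap, (nd, head))
    return dist, parent


def _restriction_arcs(net: StreetNetwork):
    """Each restriction as a tuple of directed arcs (edge_id, head_node)."""
    out = []
    for r in net.restrictions:
        nodes, eids = r.node_ids, r.edge_ids
        out.append(tuple((eids[k], nodes[k + 1]) for k in range(len(eids))))
    return out


def _state_dijkstra(net: StreetNetwork, weight, sources: dict[str, float], dest: str | None):
    """Dijkstra over arc-history states; a state is the tuple of the last
    ``h`` traversed arcs, ``h`` = (longest restriction in edges) - 1."""
    adj = net.out_arcs()
    restr = _restriction_arcs(net)
    h = max((len(r) - 1 for r in restr), default=1) or 1
    forbidden = set(restr)

    def blocked(hist, arc):
        ext = hist + (arc,)
        for r in forbidden:
            if len(ext) >= len(r) and ext[-len(r):] == r:
                return True
        return False

    dist: dict[tuple, float] = {}
    parent: dict[tuple, tuple] = {}
    node_dist: dict[str, float] = {}
    heap = []
    for s, d0 in sorted(sources.items()):
        node_dist.setdefault(s, d0)
        for eid, head, length, cls in adj[s]:
            st = ((eid, head),)
            nd = d0 + weight(length, cls)
            if nd < dist.get(st, math.inf):
                dist[st] = nd
                parent[st] = None
                heapq.heappush(heap, (nd, st))
    settled = set()
    best_dest = None
    while heap:
        d, st = heapq.heappop(heap)
        if st in settled or d > dist.get(st, math.inf):
            continue
        settled.add(st)
        head = st[-1][1]
        if head not in node_dist or d < node_dist[head]:
            node_dist[head] = d
        if dest is not None and head == dest:
            best_dest = st
            break
        for eid, nxt, length, cls in adj[head]:
            arc = (eid, nxt)
            if blocked(st, arc):
                continue
            nst = (st + (arc,))[-h:]
            nd = d + weight(length, cls)
            if nd < dist.get(nst, math.inf) - 1e-15:
                dist[nst] = nd
                parent[nst] = st
                heapq.heappush(heap, (nd, nst))
    return dist, parent, node_dist, best_dest


def _expanded_graph(net: StreetNetwork, weight, sources: dict[str, float]):
    """Explicit maneuver-expanded digraph over the same state space, for
    verification with networkx Dijkstra."""
    adj = net.out_arcs()
    restr = _restriction_arcs(net)
    h = max((len(r) - 1 for r in restr), default=1) or 1
    forbidden = set(restr)

    G = nx.DiGraph()
    frontier = []
    for s, d0 in sorted(sources.items()):
        for eid, head, length, cls in adj[s]:
            st = ((eid, head),)
            G.add_edge(("SRC", s), st, weight=weight(length, cls))
            frontier.append(st)
        G.add_node(("SRC", s))
    seen = set(frontier)
    while frontier:
        st = frontier.pop()
        head = st[-1][1]
        for eid, nxt, length, cls in adj[head]:
            arc = (eid, nxt)
            ext = st + (arc,)
            if any(len(ext) >= len(r) and ext[-len(r):] == r for r in forbidden):
                continue
            nst = ext[-h:]
            G.add_edge(st, nst, weight=weight(length, cls))
            if nst not in seen:
                seen.add(nst)
                frontier.append(nst)
    return G


def shortest_time(
    net: StreetNetwork,
    profile: SpeedProfile | None,
    origin: str,
    dest: str,
    respect_restrictions: bool = False,
    mode: str = "state",
) -> RouteResult:
    """Minimum travel time (seconds) and edge path from origin to dest.

    With ``respect_restrictions`` no returned path contains a forbidden
    maneuver; with it off, restrictions are ignored (blue-light routing).
    ``profile=None`` measures plain street-network distance in meters.
    """
    if origin not in net.nodes or dest not in net.nodes:
        raise InputError(f"origin/destination not in network: {origin}, {dest}")
    if profile is not None:
        missing = net.street_classes() - set(profile.speeds)
        if missing:
            raise ConfigurationError(f"speed profile missing classes: {sorted(missing)}")
    if origin == dest:
        return RouteResult(0.0, ())
    weight = _arc_weight(profile)

    if not respect_restrictions or not net.restrictions:
        dist, parent = _plain_dijkstra(net, weight, {origin: 0.0}, dest)
        if dest not in dist:
            return RouteResult(math.inf, None)
        path = []
        n = dest
        while n != origin:
            eid, pred = parent[n]
            path.append(eid)
            n = pred
        return RouteResult(dist[dest], tuple(reversed(path)))

    if mode == "state":
        dist, parent, _, best = _state_dijkstra(net, weight, {origin: 0.0}, dest)
        if best is None:
            return RouteResult(math.inf, None)
        # reconstruct: walk parents, collecting the newest arc of each state
        arcs = []
        st = best
        while st is not None:
            arcs.append(st[-1][0])
            st = parent[st]
        return RouteResult(dist[best], tuple(reversed(arcs)))
    elif mode == "expanded":
        G = _expanded_graph(net, weight, {origin: 0.0})
        src = ("SRC", origin)
        try:
            lengths, paths = nx.single_source_dijkstra(G, src)
        except nx.NodeNotFound:
            return RouteResult(math.inf, None)
        best_d, best_path = math.inf, None
        for st, d in lengths.items():
            if st != src and st[-1][1] == dest and d < best_d:
                best_d, best_path = d, paths[st]
        if best_path is None:
            return RouteResult(math.inf, None)
        arcs = [st[-1][0] for st in best_path[1:]]
        return RouteResult(best_d, tuple(arcs))
    raise InputError(f"unknown mode {mode!r}")


def nearest_source_times(
    net: StreetNetwork,
    profile: SpeedProfile | None,
    sources,
    respect_restrictions: bool = False,
) -> dict[str, float]:
    """Per-node minimum travel time from the nearest source (isochrone field).

    Unreachable nodes map to ``math.inf``.  Source nodes map to 0.
    """
    sources = sorted(set(sources))
    if not sources:
        raise InputError("source set must be non-empty")
    for s in sources:
        if s not in net.nodes:
            raise InputError(f"source {s} not in network")
    if profile is not None:
        missing = net.street_classes() - set(profile.speeds)
        if missing:
            raise ConfigurationError(f"speed profile missing classes: {sorted(missing)}")
    weight = _arc_weight(profile)
    init = {s: 0.0 for s in sources}
    if not respect_restrictions or not net.restrictions:
        dist, _ = _plain_dijkstra(net, weight, init, dest=None)
        field = dist
    else:
        _, _, node_dist, _ = _state_dijkstra(net, weight, init, dest=None)
        field = node_dist
    return {n: field.get(n, math.inf) for n in net.nodes}


def isochrone_edge_times(net: StreetNetwork, node_times: dict[str, float]) -> dict[str, dict]:
    """Per-edge properties for isochrone coloring: time_s = max endpoint time."""
    return {
        e.id: {"time_s": max(node_times.get(e.u, math.inf), node_times.get(e.v, math.inf))}
        for e in net.edges.values()
    }
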