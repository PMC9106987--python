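"""Street-network data structure: directed classed edges plus turn restrictions.

The network is built from OSM-style raw input — ways as node sequences with a
street-class attribute — by splitting ways at crossings and optionally
smoothing out interior degree-2 nodes whose two incident edges carry identical
attributes.  Turn restrictions (forbidden maneuvers) are stored as alternating
node–edge walks and survive construction by remapping onto the final edges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from careplan.errors import InputError

#: mean Earth radius used for the equirectangular lon/lat projection
_EARTH_R = 6_371_000.0


@dataclass(frozen=True)
class Edge:
    """One street segment.  Two-way streets are a single record traversable in
    both directions; directed arcs are derived on demand."""

    id: str
    u: str
    v: str
    length_m: float
    cls: str
    oneway: bool = False


@dataclass(frozen=True)
class TurnRestriction:
    """Forbidden maneuver: alternating walk node, edge, node, edge, node, ...

    The maneuver that traverses exactly this walk is prohibited; each edge in
    the walk must connect its flanking nodes.
    """

    via: tuple[str, ...]

    def __post_init__(self):
        if len(self.via) < 5 or len(self.via) % 2 == 0:
            raise InputError(
                f"turn restriction via-walk must be node,edge,node,... with >= 2 edges: {self.via}"
            )

    @property
    def edge_ids(self) -> tuple[str, ...]:
        return self.via[1::2]

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.via[0::2]


@dataclass
class StreetNetwork:
    nodes: dict[str, tuple[float, float]]
    edges: dict[str, Edge]
    restrictions: list[TurnRestriction] = field(default_factory=list)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for e in self.edges.values():
            if e.u not in self.nodes or e.v not in self.nodes:
                raise InputError(f"edge {e.id} references unknown node")
            if not e.length_m > 0:
                raise InputError(f"edge {e.id} has non-positive length")
        for r in self.restrictions:
            self._check_restriction_walk(r)

    def _check_restriction_walk(self, r: TurnRestriction) -> None:
        nodes, eids = r.node_ids, r.edge_ids
        for k, eid in enumerate(eids):
            e = self.edges.get(eid)
            if e is None:
                raise InputError(f"restriction references unknown edge {eid}")
            a, b = nodes[k], nodes[k + 1]
            if (e.u, e.v) != (a, b) and (e.oneway or (e.u, e.v) != (b, a)):
                raise InputError(
                    f"restriction walk not connected: edge {eid} does not join {a}->{b}"
                )

    # -- derived structure --------------------------------------------------

    def arcs(self):
        """Yield directed arcs (edge_id, tail, head, length_m, cls)."""
        for e in self.edges.values():
            yield (e.id, e.u, e.v, e.length_m, e.cls)
            if not e.oneway:
                yield (e.id, e.v, e.u, e.length_m, e.cls)

    def out_arcs(self) -> dict[str, list[tuple[str, str, float, str]]]:
        """Adjacency: node -> sorted list of (edge_id, head, length_m, cls)."""
        adj: dict[str, list] = {n: [] for n in self.nodes}
        for eid, tail, head, length, cls in self.arcs():
            adj[tail].append((eid, head, length, cls))
        for n in adj:
            adj[n].sort(key=lambda a: (a[1], a[0]))
        return adj

    def street_classes(self) -> set[str]:
        return {e.cls for e in self.edges.values()}

    def total_length(self) -> float:
        return sum(e.length_m for e in self.edges.values())

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges.values() if node in (e.u, e.v))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n, "x": x, "y": y}
                for n, (x, y) in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "id": e.id,
                    "u": e.u,
                    "v": e.v,
                    "length_m": e.length_m,
                    "class": e.cls,
                    "oneway": e.oneway,
                }
                for _, e in sorted(self.edges.items())
            ],
            "restrictions": [{"via": list(r.via)} for r in self.restrictions],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "StreetNetwork":
        net = cls(
            nodes={n["id"]: (float(n["x"]), float(n["y"])) for n in d["nodes"]},
            edges={
                e["id"]: Edge(
                    id=e["id"],
                    u=e["u"],
                    v=e["v"],
                    length_m=float(e["length_m"]),
                    cls=e["class"],
                    oneway=bool(e["oneway"]),
                )
                for e in d["edges"]
            },
            restrictions=[TurnRestriction(via=tuple(r["via"])) for r in d["restrictions"]],
        )
        net.validate()
        return net

    @classmethod
    def from_json(cls, s: str) -> "StreetNetwork":
        return cls.from_dict(json.loads(s))

    def to_geojson(self, edge_props: dict[str, dict] | None = None) -> dict:
        """Export edges as LineString features; ``edge_props`` merges extra
        per-edge properties (e.g. ``{"time_s": ...}`` for isochrone maps)."""
        features = []
        for _, e in sorted(self.edges.items()):
            props = {"id": e.id, "class": e.cls, "oneway": e.oneway, "length_m": e.length_m}
            if edge_props and e.id in edge_props:
                props.update(edge_props[e.id])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [list(self.nodes[e.u]), list(self.nodes[e.v])],
                    },
                    "properties": props,
                }
            )
        return {"type": "FeatureCollection", "features": features}


def _dist(p, q) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _project_lonlat(raw_nodes: dict) -> dict:
    """Equirectangular projection about the region centroid — adequate at
    state scale, keeps all downstream geometry in planar meters."""
    lats = [lat for (_, lat) in raw_nodes.values()]
    lat0 = math.radians(sum(lats) / len(lats))
    out = {}
    for n, (lon, lat) in raw_nodes.items():
        x = _EARTH_R * math.cos(lat0) * math.radians(lon)
        y = _EARTH_R * math.radians(lat)
        out[n] = (x, y)
    return out


def build_network(
    raw_nodes: dict[str, tuple[float, float]],
    raw_ways: list[dict],
    raw_restrictions: list[dict] | None = None,
    simplify: bool = True,
    coords: str = "xy",
) -> StreetNetwork:
    """Construct a :class:`StreetNetwork` from way-based raw input.

    Parameters
    ----------
    raw_nodes : mapping node id -> (x, y) planar meters, or (lon, lat) when
        ``coords="lonlat"``.
    raw_ways : list of ``{"id", "nodes": [...], "class", "oneway"}``.
    raw_restrictions : list of ``{"via": [node, way, node, way, node, ...]}``
        referencing way ids; remapped onto the edges of the built network.
    simplify : smooth out interior degree-2 nodes joining two edges with
        identical attributes, summing lengths.  Total length is preserved.
    """
    raw_restrictions = raw_restrictions or []
    if coords == "lonlat":
        pos = _project_lonlat(raw_nodes)
    else:
        pos = {n: (float(x), float(y)) for n, (x, y) in raw_nodes.items()}

    for w in raw_ways:
        if len(w["nodes"]) < 2:
            raise InputError(f"way {w['id']} has fewer than 2 nodes")
        for n in w["nodes"]:
            if n not in pos:
                raise InputError(f"way {w['id']} references unknown node {n}")

    # junctions: way endpoints, nodes used by >= 2 ways, nodes repeated in a
    # way, and nodes pinned by a turn restriction (never smoothed away)
    usage: dict[str, int] = {}
    for w in raw_ways:
        seen = set()
        for n in w["nodes"]:
            usage[n] = usage.get(n, 0) + (2 if n in seen else 1)
            seen.add(n)
    junctions = {n for n, c in usage.items() if c >= 2}
    for w in raw_ways:
        junctions.add(w["nodes"][0])
        junctions.add(w["nodes"][-1])
    restriction_nodes = set()
    for r in raw_restrictions:
        for n in r["via"][0::2]:
            if n not in pos:
                raise InputError(f"restriction references unknown node {n}")
            restriction_nodes.add(n)
    junctions |= restriction_nodes

    # split ways at junctions -> segments
    edges: dict[str, Edge] = {}
    way_segments: dict[str, list[str]] = {}  # way id -> ordered edge ids
    for w in raw_ways:
        wid = str(w["id"])
        cls = w.get("class", "unclassified")
        oneway = bool(w.get("oneway", False))
        nodes = w["nodes"]
        seg_start = 0
        k = 0
        segs = []
        for i in range(1, len(nodes)):
            if nodes[i] in junctions or i == len(nodes) - 1:
                chain = nodes[seg_start : i + 1]
                length = sum(_dist(pos[chain[j]], pos[chain[j + 1]]) for j in range(len(chain) - 1))
                if length <= 0:
                    raise InputError(f"way {wid} contains a zero-length segment at {chain[0]}")
                eid = f"{wid}.{k}"
                edges[eid] = Edge(eid, chain[0], chain[-1], length, cls, oneway)
                segs.append(eid)
                k += 1
                seg_start = i
        way_segments[wid] = segs

    used_nodes = {n for e in edges.values() for n in (e.u, e.v)} | junctions
    net = StreetNetwork(nodes={n: pos[n] for n in sorted(used_nodes) if n in pos}, edges=edges)

    merged_into: dict[str, str] = {}
    if simplify:
        _smooth_degree2(net, protected=restriction_nodes, merged_into=merged_into)

    def final_edge(eid: str) -> str:
        while eid in merged_into:
            eid = merged_into[eid]
        return eid

    # remap restrictions: (n0, w1, n1, w2, n2, ...) -> node-edge walk.  Each
    # flanked node pair must be joined by one surviving edge of that way.
    for r in raw_restrictions:
        via = list(r["via"])
        nodes_r = via[0::2]
        ways_r = via[1::2]
        mapped: list[str] = [nodes_r[0]]
        for k, wid in enumerate(ways_r):
            wid = str(wid)
            if wid not in way_segments:
                raise InputError(f"restriction references unknown way {wid}")
            a, b = nodes_r[k], nodes_r[k + 1]
            cands = {
                final_edge(eid)
                for eid in way_segments[wid]
                if {net.edges[final_edge(eid)].u, net.edges[final_edge(eid)].v} == {a, b}
            }
            if len(cands) != 1:
                raise InputError(
                    f"restriction via way {wid} between {a} and {b} is unmappable onto the network"
                )
            mapped.extend([cands.pop(), b])
        net.restrictions.append(TurnRestriction(via=tuple(mapped)))

    net.validate()
    return net


def _smooth_degree2(net: StreetNetwork, protected: set[str], merged_into: dict[str, str]) -> None:
    """Remove interior degree-2 nodes joining two same-attribute edges."""
    incident: dict[str, list[str]] = {}
    for e in net.edges.values():
        incident.setdefault(e.u, []).append(e.id)
        incident.setdefault(e.v, []).append(e.id)

    for n in sorted(net.nodes):
        ids = incident.get(n, [])
        if n in protected or len(ids) != 2:
            continue
        e1, e2 = (net.edges[i] for i in ids)
        if e1.cls != e2.cls or e1.oneway != e2.oneway:
            continue
        # orient the chain a -> n -> b; oneway edges must flow consistently
        if e1.oneway:
            if e1.v == n and e2.u == n:
                a, b = e1.u, e2.v
                first, second = e1, e2
            elif e2.v == n and e1.u == n:
                a, b = e2.u, e1.v
                first, second = e2, e1
            else:
                continue
        else:
            a = e1.u if e1.v == n else e1.v
            b = e2.u if e2.v == n else e2.v
            first, second = e1, e2
        if a == b or a == n or b == n:
            continue  # would create a loop
        new_id = min(first.id, second.id)
        merged = Edge(new_id, a, b, e1.length_m + e2.length_m, e1.cls, e1.oneway)
        for old in (e1.id, e2.id):
            del net.edges[old]
            if old != new_id:
                merged_into[old] = new_id
        net.edges[new_id] = merged
        del net.nodes[n]
        # update incidence
        incident[a] = [i for i in incident[a] if i not in (e1.id, e2.id)] + [new_id]
        incident[b] = [i for i in incident[b] if i not in (e1.id, e2.id)] + [new_id]
        incident.pop(n, None)
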