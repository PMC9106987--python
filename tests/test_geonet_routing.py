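"""Routing: restriction semantics, mode equivalence, isochrone fields.

The restriction-respecting oracle enumerates all simple paths up to a bounded
number of edges and takes the best duration among those avoiding every
forbidden maneuver.
"""

import itertools
import math
import random

import pytest

from careplan.errors import ConfigurationError, InputError
from careplan.geonet import (
    SpeedProfile,
    StreetNetwork,
    TurnRestriction,
    build_network,
    nearest_source_times,
    shortest_time,
)

from conftest import grid_raw, random_network


def _all_paths_durations(net, profile, origin, dest, max_edges=12):
    """Brute-force: every arc walk (no repeated arcs) origin->dest, as
    (duration, arc id sequence).  Restriction check applied by the caller."""
    adj = net.out_arcs()
    results = []

    def rec(node, arcs, used, dur):
        if node == dest and arcs:
            results.append((dur, tuple(arcs)))
        if len(arcs) >= max_edges:
            return
        for eid, head, length, cls in adj[node]:
            key = (eid, node, head)
            if key in used:
                continue
            rec(head, arcs + [(eid, head)], used | {key}, dur + profile.time_s(length, cls))

    rec(origin, [], frozenset(), 0.0)
    return results


def _violates(arcs, restrictions):
    seqs = []
    for r in restrictions:
        nodes, eids = r.node_ids, r.edge_ids
        seqs.append(tuple((eids[k], nodes[k + 1]) for k in range(len(eids))))
    for seq in seqs:
        L = len(seq)
        for i in range(len(arcs) - L + 1):
            if tuple(arcs[i : i + L]) == seq:
                return True
    return False


def test_single_edge_time():
    nodes = {"a": (0, 0), "b": (1000, 0)}
    net = build_network(nodes, [{"id": "w", "nodes": ["a", "b"], "class": "x"}])
    prof = SpeedProfile(speeds={"x": 60.0})
    res = shortest_time(net, prof, "a", "b")
    assert res.duration_s == pytest.approx(60.0)
    assert len(res.path) == 1


def test_origin_equals_dest(grid_net, uniform_profile):
    res = shortest_time(grid_net, uniform_profile, "n1_1", "n1_1")
    assert res.duration_s == 0.0
    assert res.path == ()


def test_unreachable_is_result_not_exception(uniform_profile):
    nodes = {"a": (0, 0), "b": (100, 0), "c": (0, 500), "d": (100, 500)}
    ways = [
        {"id": "w1", "nodes": ["a", "b"], "class": "minor"},
        {"id": "w2", "nodes": ["c", "d"], "class": "minor"},
    ]
    net = build_network(nodes, ways)
    res = shortest_time(net, uniform_profile, "a", "c")
    assert not res.reachable
    assert math.isinf(res.duration_s)


def test_missing_class_speed_raises(grid_net):
    with pytest.raises(ConfigurationError):
        shortest_time(grid_net, SpeedProfile(speeds={"other": 30.0}), "n0_0", "n1_0")


@pytest.mark.parametrize("mode", ["state", "expanded"])
def test_forbidden_turn_matches_path_enumeration(mode):
    """Grid with one forbidden left turn on the geodesic: the returned
    duration equals the best restriction-respecting enumerated path."""
    nodes, ways = grid_raw(4, 4, spacing=1000.0)
    net = build_network(nodes, ways, simplify=False)
    prof = SpeedProfile(speeds={"minor": 36.0})  # 100 s per 1 km edge
    origin, dest = "n0_0", "n2_2"
    base = shortest_time(net, prof, origin, dest)
    # forbid the first turning maneuver of the unrestricted geodesic
    arcs = []
    n = origin
    for eid in base.path:
        e = net.edges[eid]
        head = e.v if e.u == n else e.u
        arcs.append((eid, n, head))
        n = head
    turn = next(i for i in range(len(arcs) - 1))
    eid1, a, b = arcs[turn]
    eid2, _, c = arcs[turn + 1]
    net.restrictions.append(TurnRestriction(via=(a, eid1, b, eid2, c)))

    res = shortest_time(net, prof, origin, dest, respect_restrictions=True, mode=mode)
    cands = _all_paths_durations(net, prof, origin, dest, max_edges=8)
    ok = [d for d, p in cands if not _violates(list(p), net.restrictions)]
    assert res.duration_s == pytest.approx(min(ok), abs=1e-9)
    assert not _violates([(eid, None) for eid in res.path], [])  # path well-formed
    assert res.duration_s >= base.duration_s


def test_mode_equivalence_random_queries():
    rng = random.Random(7)
    for trial in range(5):
        net = random_network(rng, n_nodes=10, extra_edges=6)
        prof = SpeedProfile(speeds={"major": 80.0, "minor": 40.0})
        # add 2 random forbidden maneuvers
        adj = net.out_arcs()
        restr = []
        for _ in range(2):
            n = rng.choice(sorted(k for k, v in adj.items() if len(v) >= 2))
            (e1, h1, *_), (e2, h2, *_) = rng.sample(adj[n], 2)
            # maneuver arriving at n via e1 (from h1 side reversed), leaving via e2
            tail = net.edges[e1].u if net.edges[e1].v == n else net.edges[e1].v
            if tail == n or e1 == e2:
                continue
            restr.append(TurnRestriction(via=(tail, e1, n, e2, h2)))
        net.restrictions.extend(restr)
        ids = sorted(net.nodes)
        for _ in range(20):
            o, d = rng.sample(ids, 2)
            r1 = shortest_time(net, prof, o, d, respect_restrictions=True, mode="state")
            r2 = shortest_time(net, prof, o, d, respect_restrictions=True, mode="expanded")
            assert r1.duration_s == pytest.approx(r2.duration_s, abs=1e-9)


def test_restrictions_never_decrease_duration():
    rng = random.Random(11)
    net = random_network(rng, n_nodes=12, extra_edges=8)
    prof = SpeedProfile(speeds={"major": 80.0, "minor": 40.0})
    adj = net.out_arcs()
    for n in sorted(adj):
        if len(adj[n]) >= 2:
            e1 = adj[n][0][0]
            e2 = adj[n][1][0]
            tail = net.edges[e1].u if net.edges[e1].v == n else net.edges[e1].v
            head = adj[n][1][1]
            if tail != n and e1 != e2:
                net.restrictions.append(TurnRestriction(via=(tail, e1, n, e2, head)))
    ids = sorted(net.nodes)
    for _ in range(100):
        o, d = rng.sample(ids, 2)
        free = shortest_time(net, prof, o, d, respect_restrictions=False)
        restricted = shortest_time(net, prof, o, d, respect_restrictions=True)
        assert restricted.duration_s >= free.duration_s - 1e-9


def test_triangle_inequality_restriction_free():
    rng = random.Random(3)
    net = random_network(rng, n_nodes=10, extra_edges=8)
    prof = SpeedProfile(speeds={"major": 80.0, "minor": 40.0})
    ids = sorted(net.nodes)
    for a, b, c in itertools.islice(itertools.permutations(ids, 3), 60):
        dab = shortest_time(net, prof, a, b).duration_s
        dbc = shortest_time(net, prof, b, c).duration_s
        dac = shortest_time(net, prof, a, c).duration_s
        assert dac <= dab + dbc + 1e-9


def test_simplification_invariance_of_durations():
    rng = random.Random(5)
    nodes = {f"p{i}": (rng.uniform(0, 5000), rng.uniform(0, 5000)) for i in range(15)}
    ids = sorted(nodes)
    ways = []
    for w in range(12):
        k = rng.randint(2, 4)
        ways.append({"id": f"w{w}", "nodes": rng.sample(ids, k), "class": "minor"})
    raw = build_network(nodes, ways, simplify=False)
    smooth = build_network(nodes, ways, simplify=True)
    prof = SpeedProfile(speeds={"minor": 50.0})
    common = sorted(set(raw.nodes) & set(smooth.nodes))
    for _ in range(40):
        o, d = rng.sample(common, 2)
        t1 = shortest_time(raw, prof, o, d).duration_s
        t2 = shortest_time(smooth, prof, o, d).duration_s
        assert t1 == pytest.approx(t2, abs=1e-9) or (math.isinf(t1) and math.isinf(t2))


class TestNearestSourceTimes:
    def test_source_node_is_zero(self, grid_net, uniform_profile):
        field = nearest_source_times(grid_net, uniform_profile, ["n0_0"])
        assert field["n0_0"] == 0.0

    def test_field_is_elementwise_min_of_single_source_runs(self, uniform_profile):
        rng = random.Random(9)
        net = random_network(rng, n_nodes=30, extra_edges=15)
        prof = SpeedProfile(speeds={"major": 80.0, "minor": 40.0})
        sources = ["v0", "v7", "v19"]
        field = nearest_source_times(net, prof, sources)
        for n in net.nodes:
            expect = min(shortest_time(net, prof, s, n).duration_s for s in sources)
            assert field[n] == pytest.approx(expect, abs=1e-9)

    def test_disconnected_component_is_infinite(self, uniform_profile):
        nodes = {"a": (0, 0), "b": (100, 0), "c": (0, 500), "d": (100, 500)}
        ways = [
            {"id": "w1", "nodes": ["a", "b"], "class": "minor"},
            {"id": "w2", "nodes": ["c", "d"], "class": "minor"},
        ]
        net = build_network(nodes, ways)
        field = nearest_source_times(net, uniform_profile, ["a"])
        assert math.isinf(field["c"]) and math.isinf(field["d"])

    def test_empty_sources_rejected(self, grid_net, uniform_profile):
        with pytest.raises(InputError):
            nearest_source_times(grid_net, uniform_profile, [])
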