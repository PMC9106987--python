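import math
import random

import pytest

from careplan.geonet import SpeedProfile, StreetNetwork, build_network


def grid_raw(nx=4, ny=4, spacing=1000.0, cls="minor"):
    """Raw nodes/ways for an nx x ny grid; one way per row and column."""
    nodes = {f"n{i}_{j}": (i * spacing, j * spacing) for i in range(nx) for j in range(ny)}
    ways = []
    wid = 0
    for j in range(ny):
        ways.append({"id": f"r{wid}", "nodes": [f"n{i}_{j}" for i in range(nx)], "class": cls})
        wid += 1
    for i in range(nx):
        ways.append({"id": f"c{wid}", "nodes": [f"n{i}_{j}" for j in range(ny)], "class": cls})
        wid += 1
    return nodes, ways


@pytest.fixture
def grid_net():
    nodes, ways = grid_raw()
    return build_network(nodes, ways, simplify=False)


@pytest.fixture
def uniform_profile():
    return SpeedProfile(speeds={"minor": 36.0}, vehicle_type="car")


def random_network(rng: random.Random, n_nodes=12, extra_edges=8, classes=("major", "minor")):
    """Connected random network built directly (not via build_network)."""
    from careplan.geonet.network import Edge

    nodes = {f"v{i}": (rng.uniform(0, 5000), rng.uniform(0, 5000)) for i in range(n_nodes)}
    ids = sorted(nodes)
    edges = {}
    k = 0

    def add(u, v):
        nonlocal k
        length = max(1.0, math.dist(nodes[u], nodes[v]))
        edges[f"e{k}"] = Edge(f"e{k}", u, v, length, rng.choice(classes), oneway=False)
        k += 1

    for i in range(1, n_nodes):
        add(ids[i], ids[rng.randrange(i)])
    for _ in range(extra_edges):
        u, v = rng.sample(ids, 2)
        add(u, v)
    net = StreetNetwork(nodes=nodes, edges=edges)
    net.validate()
    return net
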