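"""Seeded synthetic regions and demand streams.

The real planning data (municipalities, candidate sites, historical emergency
operations, pharmacy geography, transport request streams) is confidential;
this module generates stand-ins with the statistical structure the planning
problems assume: a grid-with-diagonals street network, Voronoi municipalities
with Dirichlet-split populations, Poisson emergency arrivals placed
proportionally to population, and daily transport request streams with
plannable and ad-hoc parts.  Identical (config, seed) reproduces the region
byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from careplan.errors import InputError
from careplan.geonet import StreetNetwork, TurnRestriction, build_network
from careplan.transport.types import TransportRequest


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RegionConfig:
    grid_nx: int = 10
    grid_ny: int = 10
    spacing_m: float = 800.0
    jitter_m: float = 60.0
    major_line_prob: float = 0.3  # a whole row/column way becomes 'major'
    diagonal_prob: float = 0.12  # extra diagonal shortcut per grid cell
    n_turn_restrictions: int = 0
    n_municipalities: int = 6
    total_population: int = 60_000
    population_alpha: float = 2.0  # symmetric Dirichlet concentration
    n_candidate_sites: int = 8
    n_pharmacies: int = 14
    n_depots: int = 2
    n_hospitals: int = 1


@dataclass(frozen=True)
class Municipality:
    center_node: str
    population: int
    neighbors: tuple[str, ...]


@dataclass(frozen=True)
class Pharmacy:
    node: str
    municipality: str


@dataclass
class SyntheticRegion:
    network: StreetNetwork
    municipalities: dict[str, Municipality]
    candidate_sites: tuple[str, ...]
    pharmacies: dict[str, Pharmacy]
    depots: tuple[str, ...]
    hospitals: tuple[str, ...]
    node_municipality: dict[str, str]
    seed: int
    config: RegionConfig

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": asdict(self.config),
            "network": self.network.to_dict(),
            "municipalities": {
                m: {
                    "center_node": mu.center_node,
                    "population": mu.population,
                    "neighbors": list(mu.neighbors),
                }
                for m, mu in sorted(self.municipalities.items())
            },
            "candidate_sites": list(self.candidate_sites),
            "pharmacies": {
                p: {"node": ph.node, "municipality": ph.municipality}
                for p, ph in sorted(self.pharmacies.items())
            },
            "depots": list(self.depots),
            "hospitals": list(self.hospitals),
            "node_municipality": dict(sorted(self.node_municipality.items())),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticRegion":
        return cls(
            network=StreetNetwork.from_dict(d["network"]),
            municipalities={
                m: Municipality(v["center_node"], int(v["population"]), tuple(v["neighbors"]))
                for m, v in d["municipalities"].items()
            },
            candidate_sites=tuple(d["candidate_sites"]),
            pharmacies={
                p: Pharmacy(v["node"], v["municipality"]) for p, v in d["pharmacies"].items()
            },
            depots=tuple(d["depots"]),
            hospitals=tuple(d["hospitals"]),
            node_municipality=dict(d["node_municipality"]),
            seed=int(d["seed"]),
            config=RegionConfig(**d["config"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "SyntheticRegion":
        return cls.from_dict(json.loads(s))

    def municipality_nodes(self, mun: str) -> list[str]:
        return sorted(n for n, m in self.node_municipality.items() if m == mun)


# --------------------------------------------------------------------------
# region generation


def _largest_remainder(weights: np.ndarray, total: int, minimum: int = 0) -> np.ndarray:
    """Integer split of ``total`` proportional to ``weights`` (sums exactly)."""
    w = np.maximum(np.asarray(weights, dtype=float), 1e-12)
    w = w / w.sum()
    raw = w * (total - minimum * len(w))
    base = np.floor(raw).astype(int) + minimum
    rem = total - base.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    for i in range(rem):
        base[order[i % len(w)]] += 1
    return base


def generate_region(config: RegionConfig = RegionConfig(), seed: int = 0) -> SyntheticRegion:
    """Generate a synthetic region; deterministic in (config, seed)."""
    rng = np.random.default_rng(seed)
    nx, ny = config.grid_nx, config.grid_ny
    if config.n_municipalities > nx * ny:
        raise InputError("more municipalities than street nodes")

    def nid(i, j):
        return f"n{i}_{j}"

    raw_nodes = {}
    for i in range(nx):
        for j in range(ny):
            jx, jy = rng.uniform(-config.jitter_m, config.jitter_m, size=2)
            raw_nodes[nid(i, j)] = (i * config.spacing_m + jx, j * config.spacing_m + jy)

    ways = []
    for j in range(ny):
        cls = "major" if rng.random() < config.major_line_prob else "minor"
        ways.append({"id": f"row{j}", "nodes": [nid(i, j) for i in range(nx)], "class": cls})
    for i in range(nx):
        cls = "major" if rng.random() < config.major_line_prob else "minor"
        ways.append({"id": f"col{i}", "nodes": [nid(i, j) for j in range(ny)], "class": cls})
    d = 0
    for i in range(nx - 1):
        for j in range(ny - 1):
            if rng.random() < config.diagonal_prob:
                if rng.random() < 0.5:
                    seq = [nid(i, j), nid(i + 1, j + 1)]
                else:
                    seq = [nid(i + 1, j), nid(i, j + 1)]
                ways.append({"id": f"diag{d}", "nodes": seq, "class": "minor"})
                d += 1

    net = build_network(raw_nodes, ways, simplify=True)

    # random forbidden maneuvers at well-connected crossings
    adj = net.out_arcs()
    busy = sorted(n for n, a in adj.items() if len(a) >= 3)
    added = 0
    guard = 0
    while added < config.n_turn_restrictions and guard < 50 * max(1, config.n_turn_restrictions):
        guard += 1
        n = busy[int(rng.integers(len(busy)))]
        k1, k2 = rng.choice(len(adj[n]), size=2, replace=False)
        e1, h1 = adj[n][k1][0], adj[n][k1][1]
        e2, h2 = adj[n][k2][0], adj[n][k2][1]
        if e1 == e2 or h1 == n or h2 == n:
            continue
        # maneuver: arrive at n via e1 (from h1), leave via e2 toward h2
        r = TurnRestriction(via=(h1, e1, n, e2, h2))
        if r not in net.restrictions:
            net.restrictions.append(r)
            added += 1
    net.validate()

    node_ids = sorted(net.nodes)
    coords = np.array([net.nodes[n] for n in node_ids])

    # municipalities = Voronoi cells of M random center nodes
    centers_idx = rng.choice(len(node_ids), size=config.n_municipalities, replace=False)
    centers = [node_ids[i] for i in sorted(centers_idx)]
    mun_ids = [f"m{k}" for k in range(config.n_municipalities)]
    cx = coords[sorted(centers_idx)]
    d2 = ((coords[:, None, :] - cx[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)  # ties -> lowest municipality index
    node_municipality = {node_ids[i]: mun_ids[assign[i]] for i in range(len(node_ids))}

    pops = _largest_remainder(
        rng.dirichlet([config.population_alpha] * config.n_municipalities),
        config.total_population,
        minimum=1,
    )

    # neighbor sets from street-edge adjacency between cells
    neigh: dict[str, set[str]] = {m: set() for m in mun_ids}
    for e in net.edges.values():
        mu, mv = node_municipality[e.u], node_municipality[e.v]
        if mu != mv:
            neigh[mu].add(mv)
            neigh[mv].add(mu)

    municipalities = {
        mun_ids[k]: Municipality(
            center_node=centers[k],
            population=int(pops[k]),
            neighbors=tuple(sorted(neigh[mun_ids[k]])),
        )
        for k in range(config.n_municipalities)
    }

    sites_idx = rng.choice(len(node_ids), size=min(config.n_candidate_sites, len(node_ids)), replace=False)
    candidate_sites = tuple(node_ids[i] for i in sorted(sites_idx))

    # pharmacies allocated to municipalities proportionally to population
    ph_counts = _largest_remainder(pops, config.n_pharmacies)
    pharmacies: dict[str, Pharmacy] = {}
    k = 0
    for mk, m in enumerate(mun_ids):
        cell = [n for n in node_ids if node_municipality[n] == m]
        for _ in range(int(ph_counts[mk])):
            node = cell[int(rng.integers(len(cell)))]
            pharmacies[f"p{k:02d}"] = Pharmacy(node=node, municipality=m)
            k += 1

    depots_idx = rng.choice(len(node_ids), size=config.n_depots, replace=False)
    hosp_idx = rng.choice(len(node_ids), size=config.n_hospitals, replace=False)

    return SyntheticRegion(
        network=net,
        municipalities=municipalities,
        candidate_sites=candidate_sites,
        pharmacies=pharmacies,
        depots=tuple(node_ids[i] for i in sorted(depots_idx)),
        hospitals=tuple(node_ids[i] for i in sorted(hosp_idx)),
        node_municipality=node_municipality,
        seed=seed,
        config=config,
    )


# --------------------------------------------------------------------------
# emergency logs


@dataclass(frozen=True)
class EmergencyRecord:
    time_s: float
    node: str
    duration_s: float  # on-scene treatment
    transport: bool  # patient taken to hospital afterwards
    hospital: str | None = None


@dataclass
class EmergencyLog:
    records: tuple[EmergencyRecord, ...]

    def __post_init__(self):
        times = [r.time_s for r in self.records]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise InputError("emergency log timestamps must be non-decreasing")
        if any(r.duration_s <= 0 for r in self.records):
            raise InputError("on-scene durations must be positive")


def sample_emergencies(
    region: SyntheticRegion,
    daily_rate: float,
    horizon_days: int,
    seed: int = 0,
    duration_median_s: float = 1800.0,
    duration_sigma: float = 0.5,
    transport_prob: float = 0.5,
) -> EmergencyLog:
    """Homogeneous Poisson emergency arrivals over ``horizon_days``.

    Scene nodes are drawn proportionally to municipality population (uniform
    within the municipality); on-scene durations are log-normal with the given
    median and log-scale sigma.
    """
    if daily_rate < 0:
        raise InputError("daily rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(daily_rate * horizon_days))
    times = np.sort(rng.uniform(0.0, horizon_days * 86400.0, size=n))
    mun_ids = sorted(region.municipalities)
    pops = np.array([region.municipalities[m].population for m in mun_ids], dtype=float)
    probs = pops / pops.sum()
    cells = {m: region.municipality_nodes(m) for m in mun_ids}
    hospitals = sorted(region.hospitals)
    records = []
    for t in times:
        m = mun_ids[int(rng.choice(len(mun_ids), p=probs))]
        node = cells[m][int(rng.integers(len(cells[m])))]
        dur = float(np.exp(np.log(duration_median_s) + duration_sigma * rng.standard_normal()))
        transport = bool(rng.random() < transport_prob) and bool(hospitals)
        hosp = hospitals[int(rng.integers(len(hospitals)))] if transport else None
        records.append(EmergencyRecord(float(t), node, dur, transport, hosp))
    return EmergencyLog(records=tuple(records))


# --------------------------------------------------------------------------
# transport days


@dataclass(frozen=True)
class TransportDayConfig:
    n_plannable: int = 10
    adhoc_rate_per_h: float = 0.5
    covid_prevalence: float = 0.15
    dialysis_fraction: float = 0.3
    day_start_s: float = 6 * 3600.0
    day_end_s: float = 18 * 3600.0
    load_s: float = 300.0
    unload_s: float = 300.0
    lead_min_s: float = 600.0  # ad-hoc lead time: uniform 10-45 min
    lead_max_s: float = 2700.0


@dataclass
class TransportDay:
    plannable: tuple[TransportRequest, ...]
    adhoc: tuple[TransportRequest, ...]  # release_s < requested_s, revealed in-day

    def __post_init__(self):
        for r in self.adhoc:
            if r.release_s > r.requested_s:
                raise InputError(f"ad-hoc request {r.id} released after its requested time")


def sample_transport_day(
    region: SyntheticRegion,
    config: TransportDayConfig = TransportDayConfig(),
    seed: int = 0,
) -> TransportDay:
    """One day of transport demand: plannable requests known at day start,
    plus Poisson ad-hoc arrivals with short lead times."""
    rng = np.random.default_rng(seed)
    node_ids = sorted(region.network.nodes)

    def pair():
        i, j = rng.choice(len(node_ids), size=2, replace=False)
        return node_ids[i], node_ids[j]

    plannable = []
    for k in range(config.n_plannable):
        o, d = pair()
        plannable.append(
            TransportRequest(
                id=f"t{k:03d}",
                pickup=o,
                dropoff=d,
                requested_s=float(rng.uniform(config.day_start_s, config.day_end_s)),
                load_s=config.load_s,
                unload_s=config.unload_s,
                infectious=bool(rng.random() < config.covid_prevalence),
                dialysis=bool(rng.random() < config.dialysis_fraction),
                release_s=0.0,
            )
        )
    plannable.sort(key=lambda r: (r.requested_s, r.id))

    hours = (config.day_end_s - config.day_start_s) / 3600.0
    n_adhoc = int(rng.poisson(config.adhoc_rate_per_h * hours))
    adhoc = []
    for k in range(n_adhoc):
        o, d = pair()
        requested = float(rng.uniform(config.day_start_s, config.day_end_s))
        lead = float(rng.uniform(config.lead_min_s, config.lead_max_s))
        adhoc.append(
            TransportRequest(
                id=f"a{k:03d}",
                pickup=o,
                dropoff=d,
                requested_s=requested,
                load_s=config.load_s,
                unload_s=config.unload_s,
                infectious=bool(rng.random() < config.covid_prevalence),
                dialysis=False,
                release_s=max(config.day_start_s, requested - lead),
            )
        )
    adhoc.sort(key=lambda r: (r.release_s, r.id))
    return TransportDay(plannable=tuple(plannable), adhoc=tuple(adhoc))
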