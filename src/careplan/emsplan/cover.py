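"""q-Multiset Multicover: minimum suppliers covering integral client demands.

Suppliers are placed at candidate station locations; each supplier can serve
up to ``q`` clients in the regions its location is incident to.  Feasibility
of an allocation is a transportation problem, decided by max-flow; the
minimum allocation is a MIP with integer supplier counts and fractional
service flows (the flow polytope is integral, so fractional service variables
lose nothing).  The robust variant must stay feasible for every client vector
in a finite uncertainty set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from careplan._milp import Model
from careplan.errors import InfeasibleError, InputError


@dataclass
class CoverInstance:
    locations: tuple[str, ...]
    regions: tuple[str, ...]
    clients: dict[str, int]  # region -> demand
    incidence: set[tuple[str, str]]  # (location, region) pairs a supplier may serve
    q: int

    def __post_init__(self):
        self.locations = tuple(sorted(self.locations))
        self.regions = tuple(sorted(self.regions))
        if self.q < 1:
            raise InputError("q must be >= 1")
        for r, c in self.clients.items():
            if r not in self.regions or c < 0:
                raise InputError(f"bad client entry {r}: {c}")
        for l, r in self.incidence:
            if l not in self.locations or r not in self.regions:
                raise InputError(f"incidence ({l},{r}) references unknown ids")

    def incident_locations(self, region: str) -> list[str]:
        return sorted(l for (l, r) in self.incidence if r == region)

    def incident_regions(self, location: str) -> list[str]:
        return sorted(r for (l, r) in self.incidence if l == location)


@dataclass
class Allocation:
    suppliers: dict[str, int]

    def __post_init__(self):
        for l, s in self.suppliers.items():
            if s < 0:
                raise InputError(f"negative supplier count at {l}")

    @property
    def cost(self) -> int:
        return sum(self.suppliers.values())


@dataclass
class UncertaintySet:
    scenarios: tuple[dict[str, int], ...]

    def __post_init__(self):
        if not self.scenarios:
            raise InputError("uncertainty set must be non-empty")


@dataclass
class CoverageCheck:
    feasible: bool
    uncovered: tuple[str, ...] = ()


def check_coverage(instance: CoverInstance, alloc: Allocation, clients: dict[str, int] | None = None) -> CoverageCheck:
    """Max-flow feasibility: source -> locations (cap q*suppliers) ->
    incident regions -> sink (cap clients); feasible iff all demand flows."""
    clients = instance.clients if clients is None else clients
    total = sum(clients.get(r, 0) for r in instance.regions)
    if total == 0:
        return CoverageCheck(feasible=True)
    G = nx.DiGraph()
    for l in instance.locations:
        cap = instance.q * alloc.suppliers.get(l, 0)
        if cap > 0:
            G.add_edge("SRC", ("L", l), capacity=cap)
    for (l, r) in instance.incidence:
        G.add_edge(("L", l), ("R", r), capacity=math.inf)
    for r in instance.regions:
        c = clients.get(r, 0)
        if c > 0:
            G.add_edge(("R", r), "SNK", capacity=c)
    if "SRC" not in G or "SNK" not in G:
        uncovered = tuple(r for r in instance.regions if clients.get(r, 0) > 0)
        return CoverageCheck(feasible=False, uncovered=uncovered)
    value, flow = nx.maximum_flow(G, "SRC", "SNK")
    if value >= total:
        return CoverageCheck(feasible=True)
    uncovered = tuple(
        r
        for r in instance.regions
        if clients.get(r, 0) > 0
        and sum(flow.get(("L", l), {}).get(("R", r), 0) for l in instance.incident_locations(r))
        < clients.get(r, 0)
    )
    return CoverageCheck(feasible=False, uncovered=uncovered)


def _orphan_regions(instance: CoverInstance, clients: dict[str, int]) -> list[str]:
    return [
        r
        for r in instance.regions
        if clients.get(r, 0) > 0 and not instance.incident_locations(r)
    ]


def solve_qmsmc(instance: CoverInstance) -> Allocation:
    """Minimum total suppliers such that all clients can be served."""
    return solve_robust_qmsmc(instance, UncertaintySet(scenarios=(dict(instance.clients),)))


def solve_robust_qmsmc(instance: CoverInstance, U: UncertaintySet) -> Allocation:
    """Minimum-cost allocation feasible for every scenario in ``U``.

    One flow block per scenario shares the integer supplier variables.  Ties
    between equal-cost optima are broken toward lexicographically smaller
    location identifiers via an infinitesimal cost perturbation.
    """
    for k, scen in enumerate(U.scenarios):
        orphans = _orphan_regions(instance, scen)
        if orphans:
            raise InfeasibleError(
                f"scenario {k}: regions with demand but no incident location",
                report={"scenario": k, "regions": orphans},
            )
    mdl = Model()
    n = len(instance.locations)
    eps = 1e-4 / max(1, n)
    s_vars = {
        l: mdl.add_var(integer=True, obj=1.0 + i * eps)
        for i, l in enumerate(instance.locations)
    }
    for k, scen in enumerate(U.scenarios):
        f = {}
        for (l, r) in sorted(instance.incidence):
            f[l, r] = mdl.add_var()
        for r in instance.regions:
            c = scen.get(r, 0)
            locs = instance.incident_locations(r)
            if c > 0:
                mdl.add_constr({f[l, r]: 1.0 for l in locs}, lo=c)
        for l in instance.locations:
            coefs = {f[l, r]: 1.0 for r in instance.incident_regions(l)}
            coefs[s_vars[l]] = -float(instance.q)
            if len(coefs) > 1:
                mdl.add_constr(coefs, hi=0)
    sol = mdl.solve()
    if not sol.optimal:
        raise InfeasibleError(f"solver status {sol.status}", report={"status": sol.status})
    alloc = Allocation(
        suppliers={l: mdl.ivalue(sol, v) for l, v in s_vars.items() if mdl.ivalue(sol, v) > 0}
    )
    return alloc
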