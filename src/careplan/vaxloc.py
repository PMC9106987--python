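"""Vaccination-center location planning.

A MIP decides which candidate centers to open, assigns each municipality to
exactly one open center, and staffs every center with enough physicians for
its assigned population.  Distances are straight-line (Euclidean) between
municipality centers and candidate sites — the planning question is national/
state-scale and comparative, so street-level routing is deliberately not used
here.  Plans are evaluated by population-weighted travel-distance statistics
(the median is what the choropleth maps color).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from careplan._milp import Model
from careplan.errors import InfeasibleError, InputError


@dataclass(frozen=True)
class VaxMunicipality:
    coord: tuple[float, float]
    population: int


@dataclass
class VaccinationInstance:
    candidates: dict[str, tuple[float, float]]
    municipalities: dict[str, VaxMunicipality]
    throughput: float  # persons one physician vaccinates over the campaign
    w_centers: float = 1.0
    w_distance: float = 1e-6  # per person-meter
    w_physicians: float = 0.1
    capacity: dict[str, int] | None = None  # optional persons cap per site
    prefixed: dict[str, str] | None = None  # municipality -> forced site
    max_distance_m: float | None = None

    def __post_init__(self):
        if not self.throughput > 0:
            raise InputError("throughput must be positive")
        if self.w_centers < 0 or self.w_distance < 0 or self.w_physicians < 0:
            raise InputError("objective weights must be non-negative")
        if self.w_centers == self.w_distance == self.w_physicians == 0:
            raise InputError("at least one objective weight must be positive")
        for m, s in (self.prefixed or {}).items():
            if m not in self.municipalities or s not in self.candidates:
                raise InputError(f"prefixed assignment {m}->{s} references unknown ids")

    def dist(self, mun: str, site: str) -> float:
        return math.dist(self.municipalities[mun].coord, self.candidates[site])

    def allowed_sites(self, mun: str) -> list[str]:
        pre = (self.prefixed or {}).get(mun)
        if pre is not None:
            return [pre]
        sites = sorted(self.candidates)
        if self.max_distance_m is not None:
            sites = [s for s in sites if self.dist(mun, s) <= self.max_distance_m]
        return sites


@dataclass
class VaccinationPlan:
    open: tuple[str, ...]
    assign: dict[str, str]
    physicians: dict[str, int]
    objective: float = float("nan")

    def validate(self, instance: VaccinationInstance) -> None:
        open_set = set(self.open)
        for m in instance.municipalities:
            s = self.assign.get(m)
            if s is None:
                raise InputError(f"municipality {m} unassigned")
            if s not in open_set:
                raise InputError(f"municipality {m} assigned to closed site {s}")
        for s in open_set:
            pop = sum(
                instance.municipalities[m].population
                for m, site in self.assign.items()
                if site == s
            )
            need = math.ceil(pop / instance.throughput)
            if self.physicians.get(s, 0) < need:
                raise InputError(f"site {s} understaffed: {self.physicians.get(s, 0)} < {need}")
        for m, s in (instance.prefixed or {}).items():
            if self.assign[m] != s:
                raise InputError(f"prefixed assignment {m}->{s} not honored")


@dataclass
class PlanMetrics:
    per_municipality_m: dict[str, float]
    weighted_median_m: float
    center_count: int
    physician_total: int


def _feasibility_report(instance: VaccinationInstance) -> list[str]:
    return [m for m in sorted(instance.municipalities) if not instance.allowed_sites(m)]


def solve_center_location(
    instance: VaccinationInstance, mode: str = "weighted"
) -> VaccinationPlan:
    """Open centers, assign municipalities, staff physicians.

    ``weighted``: single solve of w_centers*|open| + w_distance*pop-weighted
    distance + w_physicians*total physicians.  ``lexicographic``: fewest
    centers first, then distance, then physicians.
    """
    bad = _feasibility_report(instance)
    if bad:
        raise InfeasibleError(
            "municipalities without any admissible site", report={"municipalities": bad}
        )
    sites = sorted(instance.candidates)
    muns = sorted(instance.municipalities)
    if not sites:
        raise InputError("at least one candidate site is required")

    def build(weights):
        w_c, w_d, w_p = weights
        mdl = Model()
        y = {s: mdl.add_var(ub=1, integer=True, obj=w_c) for s in sites}
        z = {s: mdl.add_var(integer=True, obj=w_p) for s in sites}
        x = {}
        for m in muns:
            pop = instance.municipalities[m].population
            for s in instance.allowed_sites(m):
                x[m, s] = mdl.add_var(ub=1, integer=True, obj=w_d * pop * instance.dist(m, s))
        for m in muns:
            mdl.add_constr({x[m, s]: 1.0 for s in instance.allowed_sites(m)}, lo=1, hi=1)
        for (m, s), v in x.items():
            mdl.add_constr({v: 1.0, y[s]: -1.0}, hi=0)
        for s in sites:
            coefs = {z[s]: instance.throughput}
            for m in muns:
                if (m, s) in x:
                    coefs[x[m, s]] = -instance.municipalities[m].population
            mdl.add_constr(coefs, lo=0)
        if instance.capacity:
            for s, cap in instance.capacity.items():
                coefs = {
                    x[m, s]: instance.municipalities[m].population
                    for m in muns
                    if (m, s) in x
                }
                if coefs:
                    mdl.add_constr(coefs, hi=cap)
        return mdl, y, z, x

    def extract(mdl, sol, y, z, x):
        open_sites = tuple(s for s in sites if mdl.ivalue(sol, y[s]) == 1)
        assign = {}
        for (m, s), v in x.items():
            if mdl.ivalue(sol, v) == 1:
                assign[m] = s
        physicians = {s: mdl.ivalue(sol, z[s]) for s in open_sites}
        return open_sites, assign, physicians

    if mode == "weighted":
        mdl, y, z, x = build((instance.w_centers, instance.w_distance, instance.w_physicians))
        sol = mdl.solve()
        if not sol.optimal:
            raise InfeasibleError(f"solver status {sol.status}", report={"status": sol.status})
        open_sites, assign, physicians = extract(mdl, sol, y, z, x)
        return VaccinationPlan(open_sites, assign, physicians, objective=sol.objective)
    elif mode == "lexicographic":
        # stage 1: fewest centers
        mdl, y, z, x = build((1.0, 0.0, 0.0))
        sol = mdl.solve()
        if not sol.optimal:
            raise InfeasibleError(f"solver status {sol.status}", report={"status": sol.status})
        n_centers = round(sol.objective)
        # stage 2: fix center count, minimize population-weighted distance
        mdl, y, z, x = build((0.0, 1.0, 0.0))
        mdl.add_constr({y[s]: 1.0 for s in sites}, hi=n_centers)
        sol = mdl.solve()
        if not sol.optimal:
            raise InfeasibleError(f"solver status {sol.status}", report={"status": sol.status})
        best_dist = sol.objective
        # stage 3: fix both, minimize physicians
        mdl, y, z, x = build((0.0, 0.0, 1.0))
        mdl.add_constr({y[s]: 1.0 for s in sites}, hi=n_centers)
        pops = {m: instance.municipalities[m].population for m in muns}
        mdl.add_constr(
            {v: pops[m] * instance.dist(m, s) for (m, s), v in x.items()},
            hi=best_dist + 1e-6 * max(1.0, abs(best_dist)),
        )
        sol = mdl.solve()
        if not sol.optimal:
            raise InfeasibleError(f"solver status {sol.status}", report={"status": sol.status})
        open_sites, assign, physicians = extract(mdl, sol, y, z, x)
        return VaccinationPlan(open_sites, assign, physicians, objective=sol.objective)
    raise InputError(f"unknown mode {mode!r}")


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def evaluate_plan(instance: VaccinationInstance, plan: VaccinationPlan) -> PlanMetrics:
    plan.validate(instance)
    muns = sorted(instance.municipalities)
    dists = {m: instance.dist(m, plan.assign[m]) for m in muns}
    pops = [instance.municipalities[m].population for m in muns]
    return PlanMetrics(
        per_municipality_m=dists,
        weighted_median_m=weighted_median([dists[m] for m in muns], pops),
        center_count=len(plan.open),
        physician_total=sum(plan.physicians.values()),
    )


def plan_to_geojson(instance: VaccinationInstance, plan: VaccinationPlan) -> dict:
    """Allocation chart: one Point per open site (radius ~ physicians) and one
    LineString per municipality -> assigned site."""
    features = []
    for s in plan.open:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(instance.candidates[s])},
                "properties": {"site": s, "physicians": plan.physicians.get(s, 0)},
            }
        )
    metrics = evaluate_plan(instance, plan)
    for m in sorted(instance.municipalities):
        s = plan.assign[m]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        list(instance.municipalities[m].coord),
                        list(instance.candidates[s]),
                    ],
                },
                "properties": {
                    "municipality": m,
                    "site": s,
                    "median_km": metrics.per_municipality_m[m] / 1000.0,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
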