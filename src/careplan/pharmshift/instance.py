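"""Out-of-hours pharmacy rostering: instance data and plan container.

A plan assigns each pharmacy a set of 24-hour duty days over the horizon.
Constraint families: coverage (enough open pharmacies within reach of every
municipality every day, with a surplus absorbing quarantine closures),
geographic dispersion (no two open pharmacies in vicinity of each other on
the same day), rest periods between consecutive services, a legal minimum of
annual services per pharmacy, and fairness brackets tied to an idealized
lexicographically fair load vector.

Reachability and vicinity use street-network distance in meters; instances
carry the precomputed distance tables so solvers and oracles need no routing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from careplan.errors import InputError


@dataclass(frozen=True)
class RosterPharmacy:
    node: str | None
    municipality: str


@dataclass
class PharmacyInstance:
    pharmacies: dict[str, RosterPharmacy]
    municipalities: dict[str, tuple[str | None, tuple[str, ...]]]  # id -> (center node, neighbors)
    horizon_days: int
    coverage_radius_m: float
    coverage_count: int = 1  # c: distinct in-range pharmacies per municipality-day
    vicinity_radius_m: float = 0.0  # V: no two open within V on the same day
    rest_days: int = 0  # r: duty on day t forbids t+1..t+r
    min_annual_services: int = 0  # s_min
    fairness_slack: float = 0.2  # delta
    quarantine_budget: int = 0  # gamma: surplus coverage absorbing closures
    dist_pm: dict[tuple[str, str], float] = field(default_factory=dict)  # (pharmacy, municipality) -> m
    dist_pp: dict[frozenset, float] = field(default_factory=dict)  # {p1, p2} -> m

    def __post_init__(self):
        if self.horizon_days < 1:
            raise InputError("horizon must be >= 1 day")
        if self.coverage_radius_m < 0 or self.vicinity_radius_m < 0:
            raise InputError("radii must be >= 0")
        if self.rest_days < 0 or self.quarantine_budget < 0:
            raise InputError("rest period and quarantine budget must be >= 0")
        if self.coverage_count < 1:
            raise InputError("coverage count must be >= 1")
        for p, ph in self.pharmacies.items():
            if ph.municipality not in self.municipalities:
                raise InputError(f"pharmacy {p} in unknown municipality {ph.municipality}")

    # -- derived geometry --------------------------------------------------

    @cached_property
    def pharmacy_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.pharmacies))

    @cached_property
    def municipality_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.municipalities))

    @cached_property
    def required_coverage(self) -> int:
        return self.coverage_count + self.quarantine_budget

    @cached_property
    def cover(self) -> dict[str, tuple[str, ...]]:
        """Municipality -> pharmacies within the coverage radius."""
        out = {}
        for m in self.municipality_ids:
            out[m] = tuple(
                p
                for p in self.pharmacy_ids
                if self.dist_pm.get((p, m), math.inf) <= self.coverage_radius_m
            )
        return out

    @cached_property
    def covered_by(self) -> dict[str, tuple[str, ...]]:
        """Pharmacy -> municipalities it covers."""
        out = {p: [] for p in self.pharmacy_ids}
        for m, ps in self.cover.items():
            for p in ps:
                out[p].append(m)
        return {p: tuple(sorted(v)) for p, v in out.items()}

    @cached_property
    def conflicts(self) -> tuple[frozenset, ...]:
        """Unordered pharmacy pairs forbidden to serve the same day."""
        if self.vicinity_radius_m <= 0:
            return ()
        out = []
        ids = self.pharmacy_ids
        for i, p in enumerate(ids):
            for q in ids[i + 1 :]:
                d = self.dist_pp.get(frozenset((p, q)), math.inf)
                if d <= self.vicinity_radius_m:
                    out.append(frozenset((p, q)))
        return tuple(out)

    def conflict_partners(self, p: str) -> tuple[str, ...]:
        return tuple(sorted(q for pair in self.conflicts if p in pair for q in pair if q != p))

    def structural_report(self) -> dict:
        """First-order infeasibility diagnosis, independent of any solver."""
        problems = {"coverage": [], "rest_vs_minimum": []}
        for m in self.municipality_ids:
            if len(self.cover[m]) < self.required_coverage:
                problems["coverage"].append(m)
        cap = math.ceil(self.horizon_days / (self.rest_days + 1))
        if self.min_annual_services > cap:
            problems["rest_vs_minimum"] = list(self.pharmacy_ids)
        return {k: v for k, v in problems.items() if v}


@dataclass
class DutyPlan:
    """Pharmacy x day 0/1 duty matrix."""

    pharmacy_ids: tuple[str, ...]
    horizon_days: int
    duty: np.ndarray  # bool (P, T)

    def __post_init__(self):
        self.duty = np.asarray(self.duty, dtype=bool)
        if self.duty.shape != (len(self.pharmacy_ids), self.horizon_days):
            raise InputError("duty matrix shape does not match pharmacies x days")

    @property
    def totals(self) -> dict[str, int]:
        return {p: int(self.duty[i].sum()) for i, p in enumerate(self.pharmacy_ids)}

    @property
    def total_services(self) -> int:
        return int(self.duty.sum())

    def open_on(self, day: int) -> tuple[str, ...]:
        return tuple(p for i, p in enumerate(self.pharmacy_ids) if self.duty[i, day])

    def index(self, p: str) -> int:
        return self.pharmacy_ids.index(p)


@dataclass(frozen=True)
class IdealizedLoads:
    """Annual service counts of the simplified (coverage-only) problem whose
    sorted-descending vector is lexicographically minimal."""

    load: dict[str, int]

    def sorted_desc(self) -> tuple[int, ...]:
        return tuple(sorted(self.load.values(), reverse=True))


def instance_from_region(
    region,
    horizon_days: int,
    coverage_radius_m: float,
    coverage_count: int = 1,
    vicinity_radius_m: float = 0.0,
    rest_days: int = 1,
    min_annual_services: int = 0,
    fairness_slack: float = 0.2,
    quarantine_budget: int = 0,
) -> PharmacyInstance:
    """Build a rostering instance from a synthetic region, measuring
    reachability and vicinity along the street network (meters)."""
    from careplan.geonet import nearest_source_times

    net = region.network
    dist_pm: dict[tuple[str, str], float] = {}
    dist_pp: dict[frozenset, float] = {}
    # municipality centers -> all nodes (distance field per center)
    for m, mu in sorted(region.municipalities.items()):
        field_m = nearest_source_times(net, None, [mu.center_node])
        for p, ph in region.pharmacies.items():
            dist_pm[(p, m)] = field_m.get(ph.node, math.inf)
    if vicinity_radius_m > 0:
        items = sorted(region.pharmacies.items())
        fields = {p: nearest_source_times(net, None, [ph.node]) for p, ph in items}
        for i, (p, ph) in enumerate(items):
            for q, qh in items[i + 1 :]:
                dist_pp[frozenset((p, q))] = min(
                    fields[p].get(qh.node, math.inf), fields[q].get(ph.node, math.inf)
                )
    return PharmacyInstance(
        pharmacies={
            p: RosterPharmacy(node=ph.node, municipality=ph.municipality)
            for p, ph in region.pharmacies.items()
        },
        municipalities={
            m: (mu.center_node, mu.neighbors) for m, mu in region.municipalities.items()
        },
        horizon_days=horizon_days,
        coverage_radius_m=coverage_radius_m,
        coverage_count=coverage_count,
        vicinity_radius_m=vicinity_radius_m,
        rest_days=rest_days,
        min_annual_services=min_annual_services,
        fairness_slack=fairness_slack,
        quarantine_budget=quarantine_budget,
        dist_pm=dist_pm,
        dist_pp=dist_pp,
    )
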