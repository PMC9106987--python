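"""Independent plan validation and decision-support statistics.

``validate_plan`` re-checks every constraint family with plain double loops,
deliberately sharing no code with the solver, and computes the fairness
statistics shown to planners (within-municipality maximum difference and
each pharmacy's difference to its municipality average).
``reachability_stats`` recomputes, day by day, the street-network distance
from each municipality center to the nearest open pharmacy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from careplan.pharmshift.instance import DutyPlan, IdealizedLoads, PharmacyInstance
from careplan.pharmshift.planning import fairness_bounds


@dataclass
class ValidationReport:
    coverage: list = field(default_factory=list)  # (municipality, day, open count)
    dispersion: list = field(default_factory=list)  # (p, q, day)
    rest: list = field(default_factory=list)  # (p, day1, day2)
    minimum_services: list = field(default_factory=list)  # (p, total)
    fairness: list = field(default_factory=list)  # (p, total, lo, hi)
    within_municipality_max_diff: dict[str, int] = field(default_factory=dict)
    diff_to_municipality_avg: dict[str, float] = field(default_factory=dict)

    @property
    def violation_count(self) -> int:
        return (
            len(self.coverage)
            + len(self.dispersion)
            + len(self.rest)
            + len(self.minimum_services)
            + len(self.fairness)
        )

    @property
    def feasible(self) -> bool:
        return self.violation_count == 0


def validate_plan(
    instance: PharmacyInstance,
    plan: DutyPlan,
    fairness: IdealizedLoads | None = None,
) -> ValidationReport:
    report = ValidationReport()
    T = instance.horizon_days
    need = instance.required_coverage
    open_by_day = [set(plan.open_on(d)) for d in range(T)]

    for d in range(T):
        for m in instance.municipality_ids:
            n_open = sum(1 for p in instance.cover[m] if p in open_by_day[d])
            if n_open < need:
                report.coverage.append((m, d, n_open))
    for d in range(T):
        for pair in instance.conflicts:
            p, q = sorted(pair)
            if p in open_by_day[d] and q in open_by_day[d]:
                report.dispersion.append((p, q, d))
    r = instance.rest_days
    for i, p in enumerate(plan.pharmacy_ids):
        days = [d for d in range(T) if plan.duty[i, d]]
        for d1, d2 in zip(days, days[1:]):
            if d2 - d1 <= r:
                report.rest.append((p, d1, d2))
    totals = plan.totals
    for p, tot in totals.items():
        if tot < instance.min_annual_services:
            report.minimum_services.append((p, tot))
    if fairness is not None:
        for p, (lo, hi) in fairness_bounds(instance, fairness).items():
            if not (lo <= totals.get(p, 0) <= hi):
                report.fairness.append((p, totals.get(p, 0), lo, hi))

    by_mun: dict[str, list[int]] = {}
    for p, tot in totals.items():
        by_mun.setdefault(instance.pharmacies[p].municipality, []).append(tot)
    for m, vals in by_mun.items():
        report.within_municipality_max_diff[m] = max(vals) - min(vals)
    for p, tot in totals.items():
        vals = by_mun[instance.pharmacies[p].municipality]
        report.diff_to_municipality_avg[p] = tot - sum(vals) / len(vals)
    return report


@dataclass
class ReachabilityStats:
    median_m: dict[str, float]
    min_m: dict[str, float]
    max_m: dict[str, float]
    uncovered_days: dict[str, int]  # days with no reachable open pharmacy


def reachability_stats(instance: PharmacyInstance, plan: DutyPlan) -> ReachabilityStats:
    """Per municipality, the distribution over days of the street-network
    distance to the nearest open pharmacy (meters); days with no reachable
    pharmacy count as uncovered and enter the statistics as +inf."""
    med, mn, mx, unc = {}, {}, {}, {}
    for m in instance.municipality_ids:
        daily = []
        bad = 0
        for d in range(plan.horizon_days):
            dists = [
                instance.dist_pm.get((p, m), math.inf) for p in plan.open_on(d)
            ]
            best = min(dists) if dists else math.inf
            if math.isinf(best):
                bad += 1
            daily.append(best)
        med[m] = float(np.median(daily)) if daily else math.inf
        mn[m] = float(min(daily)) if daily else math.inf
        mx[m] = float(max(daily)) if daily else math.inf
        unc[m] = bad
    return ReachabilityStats(median_m=med, min_m=mn, max_m=mx, uncovered_days=unc)


def plan_to_geojson(instance: PharmacyInstance, plan: DutyPlan, region=None) -> dict:
    """Marker/fairness/reachability chart export.

    Pharmacy Points carry total services and the difference to the
    municipality average; municipality Points carry the within-municipality
    maximum difference and the annual median reachability distance.
    Coordinates require a region (node positions); without one, indices are
    used as placeholder coordinates.
    """
    report = validate_plan(instance, plan)
    reach = reachability_stats(instance, plan)
    totals = plan.totals

    def node_xy(node, k):
        if region is not None and node in region.network.nodes:
            return list(region.network.nodes[node])
        return [float(k), 0.0]

    features = []
    for k, p in enumerate(plan.pharmacy_ids):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": node_xy(instance.pharmacies[p].node, k),
                },
                "properties": {
                    "pharmacy": p,
                    "total_services": totals[p],
                    "diff_to_municipality_avg": report.diff_to_municipality_avg[p],
                },
            }
        )
    for k, m in enumerate(instance.municipality_ids):
        center = instance.municipalities[m][0]
        median = reach.median_m[m]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": node_xy(center, k)},
                "properties": {
                    "municipality": m,
                    "max_within_difference": report.within_municipality_max_diff.get(m, 0),
                    "median_km": None if math.isinf(median) else median / 1000.0,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
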