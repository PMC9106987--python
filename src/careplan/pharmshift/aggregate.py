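"""Aggregation of mathematically equivalent pharmacies.

Two pharmacies are equivalent when they sit in the same municipality, cover
the same municipality set within the reach radius, and have the same
vicinity-conflict structure.  Each class is replaced by one representative
with a multiplicity; the aggregated roster uses integer open-counts per
class-day with sliding-window rest capacity (every window of rest+1 days
admits at most one service per member), which is exact: round-robin
disaggregation in chronological order restores a feasible member-level plan
with the same total.  Besides shrinking the model, aggregation breaks the
permutation symmetry among identical pharmacies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from careplan._milp import Model
from careplan.errors import InfeasibleError
from careplan.pharmshift.instance import DutyPlan, PharmacyInstance


@dataclass
class Aggregation:
    classes: dict[str, tuple[str, ...]]  # representative -> members (sorted)
    representative_of: dict[str, str]

    @property
    def multiplicity(self) -> dict[str, int]:
        return {rep: len(members) for rep, members in self.classes.items()}


def aggregate_pharmacies(instance: PharmacyInstance) -> Aggregation:
    """Partition pharmacies into equivalence classes by iterated refinement
    (municipality + covered set first, then conflict structure to fixpoint)."""
    P = instance.pharmacy_ids
    color = {
        p: (instance.pharmacies[p].municipality, instance.covered_by[p]) for p in P
    }
    while True:
        new_color = {}
        for p in P:
            partners = tuple(sorted({color[q] for q in instance.conflict_partners(p)}, key=repr))
            internal = any(
                color[q] == color[p] for q in instance.conflict_partners(p)
            )
            new_color[p] = (color[p], partners, internal)
        if len(set(new_color.values())) == len(set(color.values())):
            break
        color = new_color
    groups: dict = {}
    for p in P:
        groups.setdefault(color[p], []).append(p)
    classes = {}
    rep_of = {}
    for members in groups.values():
        members = sorted(members)
        rep = members[0]
        classes[rep] = tuple(members)
        for m in members:
            rep_of[m] = rep
    return classes_to_aggregation(classes, rep_of)


def classes_to_aggregation(classes, rep_of) -> Aggregation:
    return Aggregation(classes=classes, representative_of=rep_of)


def solve_duty_plan_aggregated(instance: PharmacyInstance) -> DutyPlan:
    """Aggregated exact solve (without fairness brackets) + disaggregation."""
    agg = aggregate_pharmacies(instance)
    reps = sorted(agg.classes)
    T = instance.horizon_days
    mult = agg.multiplicity
    r = instance.rest_days
    need = instance.required_coverage

    bad = [m for m in instance.municipality_ids if len(instance.cover[m]) < need]
    if bad:
        raise InfeasibleError(
            "municipalities without enough pharmacies in reach",
            report={"family": "coverage", "municipalities": bad},
        )

    # class-level conflict structure
    internal_conflict = {}
    cross_conflict = set()
    for rep in reps:
        members = agg.classes[rep]
        internal_conflict[rep] = any(
            frozenset((a, b)) in set(instance.conflicts)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
    for pair in instance.conflicts:
        p, q = sorted(pair)
        rp, rq = agg.representative_of[p], agg.representative_of[q]
        if rp != rq:
            cross_conflict.add(frozenset((rp, rq)))

    mdl = Model()
    z = {}
    for rep in reps:
        cap = 1 if internal_conflict[rep] else mult[rep]
        for d in range(T):
            z[rep, d] = mdl.add_var(ub=cap, integer=True, obj=1.0)
    # coverage: classes covering m contribute their open counts
    cover_reps = {
        m: sorted({agg.representative_of[p] for p in instance.cover[m]})
        for m in instance.municipality_ids
    }
    for d in range(T):
        for m in instance.municipality_ids:
            mdl.add_constr({z[rep, d]: 1.0 for rep in cover_reps[m]}, lo=need)
    # cross-class vicinity: not both classes open on a day
    o = {}
    if cross_conflict:
        involved = sorted({rep for pair in cross_conflict for rep in pair})
        for rep in involved:
            for d in range(T):
                o[rep, d] = mdl.add_var(ub=1, integer=True)
                mdl.add_constr({z[rep, d]: 1.0, o[rep, d]: -float(mult[rep])}, hi=0)
        for pair in sorted(cross_conflict, key=sorted):
            a, b = sorted(pair)
            for d in range(T):
                mdl.add_constr({o[a, d]: 1.0, o[b, d]: 1.0}, hi=1)
    # rest: any (r+1)-day window serves each member at most once
    if r > 0:
        for rep in reps:
            for d0 in range(T - r):
                mdl.add_constr(
                    {z[rep, d]: 1.0 for d in range(d0, min(T, d0 + r + 1))}, hi=mult[rep]
                )
    # minimum annual services per member
    if instance.min_annual_services > 0:
        for rep in reps:
            mdl.add_constr(
                {z[rep, d]: 1.0 for d in range(T)},
                lo=mult[rep] * instance.min_annual_services,
            )
    sol = mdl.solve()
    if not sol.optimal:
        raise InfeasibleError("aggregated duty plan infeasible", report={"status": sol.status})

    # disaggregate: chronological round-robin within each class
    P = instance.pharmacy_ids
    mat = np.zeros((len(P), T), dtype=bool)
    index = {p: i for i, p in enumerate(P)}
    for rep in reps:
        members = agg.classes[rep]
        k = 0
        for d in range(T):
            count = mdl.ivalue(sol, z[rep, d])
            for _ in range(count):
                mat[index[members[k % len(members)]], d] = True
                k += 1
    return DutyPlan(pharmacy_ids=P, horizon_days=T, duty=mat)
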