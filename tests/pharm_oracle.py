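"""Exhaustive roster oracles: enumerate every 0/1 plan as a bit pattern.

Bit layout: pharmacy index p, day d -> bit p*T + d.  All constraint checks
are vectorized over the full plan enumeration with popcounts, independent of
the MIP formulation.
"""

import math

import numpy as np

from careplan.pharmshift import PharmacyInstance, RosterPharmacy
from careplan.pharmshift.planning import fairness_bounds


def toy_instance(
    cover_map: dict[str, list[str]],
    T: int,
    c: int = 1,
    conflicts: list[tuple[str, str]] = (),
    rest_days: int = 0,
    s_min: int = 0,
    gamma: int = 0,
    delta: float = 0.2,
    municipality_of: dict[str, str] | None = None,
) -> PharmacyInstance:
    """Instance from explicit cover sets/conflict pairs (distance-free)."""
    pharmacies = sorted({p for ps in cover_map.values() for p in ps})
    if municipality_of is None:
        municipality_of = {}
    first_mun = sorted(cover_map)[0]
    dist_pm = {}
    for m, ps in cover_map.items():
        for p in pharmacies:
            dist_pm[(p, m)] = 0.0 if p in ps else math.inf
    dist_pp = {frozenset(pair): 0.5 for pair in conflicts}
    return PharmacyInstance(
        pharmacies={
            p: RosterPharmacy(node=None, municipality=municipality_of.get(p, first_mun))
            for p in pharmacies
        },
        municipalities={m: (None, ()) for m in cover_map},
        horizon_days=T,
        coverage_radius_m=1.0,
        coverage_count=c,
        vicinity_radius_m=1.0 if conflicts else 0.0,
        rest_days=rest_days,
        min_annual_services=s_min,
        fairness_slack=delta,
        quarantine_budget=gamma,
        dist_pm=dist_pm,
        dist_pp=dist_pp,
    )


def _bit(instance, p, d):
    T = instance.horizon_days
    return 1 << (instance.pharmacy_ids.index(p) * T + d)


def feasible_mask(instance: PharmacyInstance, fairness=None, coverage_only=False):
    """Boolean mask over all 2^(P*T) plans: feasibility per constraint family."""
    P = instance.pharmacy_ids
    T = instance.horizon_days
    n = len(P) * T
    assert n <= 26, "enumeration oracle limited to 2^26 plans"
    plans = np.arange(1 << n, dtype=np.uint32)
    ok = np.ones(plans.shape, dtype=bool)
    need = instance.required_coverage
    for d in range(T):
        for m in instance.municipality_ids:
            mask = np.uint32(sum(_bit(instance, p, d) for p in instance.cover[m]))
            ok &= np.bitwise_count(plans & mask) >= need
    if not coverage_only:
        for d in range(T):
            for pair in instance.conflicts:
                p, q = sorted(pair)
                mask = np.uint32(_bit(instance, p, d) | _bit(instance, q, d))
                ok &= (plans & mask) != mask
        r = instance.rest_days
        if r > 0:
            for p in P:
                for d1 in range(T):
                    for d2 in range(d1 + 1, min(T, d1 + r + 1)):
                        mask = np.uint32(_bit(instance, p, d1) | _bit(instance, p, d2))
                        ok &= (plans & mask) != mask
        if instance.min_annual_services > 0:
            for p in P:
                mask = np.uint32(sum(_bit(instance, p, d) for d in range(T)))
                ok &= np.bitwise_count(plans & mask) >= instance.min_annual_services
        if fairness is not None:
            for p, (lo, hi) in fairness_bounds(instance, fairness).items():
                mask = np.uint32(sum(_bit(instance, p, d) for d in range(T)))
                tot = np.bitwise_count(plans & mask)
                ok &= (tot >= lo) & (tot <= hi)
    return plans, ok


def min_total_services(instance: PharmacyInstance, fairness=None):
    """Exhaustive optimum of the full roster problem; None if infeasible."""
    plans, ok = feasible_mask(instance, fairness=fairness)
    if not ok.any():
        return None
    return int(np.bitwise_count(plans[ok]).min())


def lex_min_sorted_loads(instance: PharmacyInstance):
    """Lexicographically minimal sorted-descending load vector over all
    plans feasible for the coverage-only (simplified) problem."""
    plans, ok = feasible_mask(instance, coverage_only=True)
    if not ok.any():
        return None
    sub = plans[ok]
    P = instance.pharmacy_ids
    T = instance.horizon_days
    loads = np.empty((len(P), len(sub)), dtype=np.int16)
    for i, p in enumerate(P):
        mask = np.uint32(sum(_bit(instance, p, d) for d in range(T)))
        loads[i] = np.bitwise_count(sub & mask)
    loads = -np.sort(-loads, axis=0)  # sorted descending per plan
    order = np.lexsort(loads[::-1])  # row 0 is the primary key
    return tuple(int(x) for x in loads[:, order[0]])
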