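"""Patient transport: lexicographic VRP oracle equivalence, online re-solve,
dummy returns, fleet separation, metrics."""

import math
import random

import pytest

from careplan.errors import InfeasibleError
from careplan.transport import (
    DayState,
    Stop,
    TransportRequest,
    TransportSchedule,
    Vehicle,
    make_dummy_returns,
    reoptimize,
    schedule_metrics,
    simulate_transport_day,
    solve_vrpgtw,
)
from careplan.synthgeo import TransportDay

from transport_oracle import EuclidTau, brute_force_vrpgtw

H = 3600.0


def points5(rng=None):
    pts = {
        "depot": (0.0, 0.0),
        "A": (3000.0, 0.0),
        "B": (0.0, 4000.0),
        "C": (3000.0, 4000.0),
        "D": (-2000.0, 1000.0),
    }
    if rng:
        pts = {k: (x + rng.uniform(-500, 500), y + rng.uniform(-500, 500)) for k, (x, y) in pts.items()}
    return pts


def veh(vid="v0", fleet="clean", start=6 * H, end=20 * H, depot="depot", **kw):
    return Vehicle(id=vid, depot=depot, shift_start_s=start, shift_end_s=end, fleet=fleet, **kw)


def req(rid, pickup, dropoff, t, load=120.0, unload=120.0, **kw):
    return TransportRequest(
        id=rid, pickup=pickup, dropoff=dropoff, requested_s=t, load_s=load, unload_s=unload, **kw
    )


@pytest.fixture
def tau():
    return EuclidTau(points5())


def rand_requests(rng, n, tau, infectious_p=0.0):
    names = [k for k in tau.points if k != "depot"]
    out = []
    for i in range(n):
        a, b = rng.sample(names, 2)
        out.append(
            req(
                f"r{i}",
                a,
                b,
                rng.uniform(8 * H, 16 * H),
                infectious=rng.random() < infectious_p,
            )
        )
    return out


class TestSolve:
    def test_reachable_request_zero_delay_no_early_pickup(self, tau):
        r = req("r0", "A", "B", 10 * H)
        sched = solve_vrpgtw([r], [veh()], tau=tau)
        stop = sched.routes["v0"][0]
        assert sched.delays["r0"] == 0.0
        assert stop.pickup_start_s == pytest.approx(10 * H)  # waits, never early

    def test_request_before_shift_start_forced_delay(self, tau):
        r = req("r0", "A", "B", 5 * H)  # one hour before shift opens
        sched = solve_vrpgtw([r], [veh()], tau=tau)
        expected = (6 * H + tau("depot", "A")) - 5 * H
        assert sched.delays["r0"] == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(61)
        for trial in range(6):
            t = EuclidTau(points5(rng))
            requests = rand_requests(rng, 4, t)
            vehicles = [veh("v0"), veh("v1", start=7 * H)]
            sched = solve_vrpgtw(requests, vehicles, tau=t)
            want = brute_force_vrpgtw(requests, vehicles, t)
            assert (sched.d_max, sched.total_delay) == pytest.approx(want, abs=1e-6)

    def test_adding_request_never_decreases_dmax(self, tau):
        rng = random.Random(62)
        requests = rand_requests(rng, 3, tau)
        vehicles = [veh("v0")]
        base = solve_vrpgtw(requests, vehicles, tau=tau)
        extra = requests + [req("rx", "C", "A", 12 * H)]
        more = solve_vrpgtw(extra, vehicles, tau=tau)
        assert more.d_max >= base.d_max - 1e-9

    def test_infeasible_lists_unservable_requests(self, tau):
        r = req("r0", "A", "B", 10 * H, infectious=True)
        with pytest.raises(InfeasibleError) as e:
            solve_vrpgtw([r], [veh(fleet="clean")], tau=tau)
        assert e.value.report["requests"] == ["r0"]

    def test_fleet_separation_without_floaters(self, tau):
        rng = random.Random(63)
        requests = rand_requests(rng, 4, tau, infectious_p=0.5)
        if not any(r.infectious for r in requests):
            requests[0] = req("r0", "A", "B", 9 * H, infectious=True)
        vehicles = [veh("v0", fleet="clean"), veh("v1", fleet="covid")]
        try:
            sched = solve_vrpgtw(requests, vehicles, tau=tau)
        except InfeasibleError:
            return
        byid = {r.id: r for r in requests}
        for vid, stops in sched.routes.items():
            cats = {byid[s.request_id].infectious for s in stops}
            assert len(cats) <= 1

    def test_covid_addon_monotone_in_total_delay(self, tau):
        rng = random.Random(64)
        requests = rand_requests(rng, 3, tau, infectious_p=1.0)
        lo = solve_vrpgtw(requests, [veh(fleet="covid", covid_addon_s=60.0)], tau=tau)
        hi = solve_vrpgtw(requests, [veh(fleet="covid", covid_addon_s=1200.0)], tau=tau)
        assert hi.total_delay >= lo.total_delay - 1e-9


class TestReoptimize:
    def _state(self, tau, requests, vehicles):
        sched = solve_vrpgtw(requests, vehicles, tau=tau)
        return sched

    def test_idempotent_without_new_requests(self, tau):
        rng = random.Random(65)
        requests = rand_requests(rng, 3, tau)
        vehicles = [veh("v0"), veh("v1")]
        incumbent = solve_vrpgtw(requests, vehicles, tau=tau)
        state = DayState(
            now_s=6 * H,
            executed={v.id: [] for v in vehicles},
            positions={v.id: (v.depot, v.shift_start_s) for v in vehicles},
            outstanding=requests,
        )
        again = reoptimize(state, [], vehicles, tau=tau)
        assert again.delays == incumbent.delays
        assert (again.d_max, again.total_delay) == (incumbent.d_max, incumbent.total_delay)

    def test_executed_prefix_unchanged(self, tau):
        vehicles = [veh("v0")]
        done = [Stop("r0", 8 * H, 8.5 * H, executed=True)]
        state = DayState(
            now_s=9 * H,
            executed={"v0": done},
            positions={"v0": ("B", 8.5 * H)},
            outstanding=[req("r1", "A", "C", 10 * H)],
        )
        sched = reoptimize(state, [req("r2", "C", "A", 11 * H)], vehicles, tau=tau)
        assert sched.routes["v0"][0].request_id == "r0"
        assert sched.routes["v0"][0].pickup_start_s == 8 * H
        assert sched.routes["v0"][0].executed

    def test_optimal_among_prefix_respecting_schedules(self, tau):
        # vehicle anchored mid-day at B; outstanding + one ad-hoc
        vehicles = [veh("v0")]
        outstanding = [req("r1", "A", "C", 11 * H), req("r2", "C", "D", 12 * H)]
        adhoc = req("rx", "B", "A", 11.5 * H, release_s=11 * H)
        state = DayState(
            now_s=11 * H,
            executed={"v0": [Stop("r0", 10 * H, 10.6 * H, executed=True)]},
            positions={"v0": ("B", 10.6 * H)},
            outstanding=outstanding,
        )
        sched = reoptimize(state, [adhoc], vehicles, tau=tau)
        want = brute_force_vrpgtw(
            outstanding + [adhoc], vehicles, tau, anchors={"v0": ("B", 10.6 * H)}
        )
        assert (sched.d_max, sched.total_delay) == pytest.approx(want, abs=1e-6)

    def test_unservable_new_request_flagged_not_fatal(self, tau):
        vehicles = [veh("v0", fleet="clean")]
        state = DayState(
            now_s=9 * H,
            executed={"v0": []},
            positions={"v0": ("depot", 9 * H)},
            outstanding=[req("r1", "A", "B", 10 * H)],
        )
        sched = reoptimize(
            state, [req("rx", "B", "C", 11 * H, infectious=True)], vehicles, tau=tau
        )
        assert sched.unserved == ("rx",)
        assert "r1" in sched.delays


class TestDummies:
    def test_dialysis_spawns_swapped_return(self):
        r = req("d0", "A", "B", 8 * H, dialysis=True)
        (dummy,) = make_dummy_returns([r], stay_estimate=lambda r: 240 * 60.0)
        assert dummy.pickup == "B" and dummy.dropoff == "A"
        assert dummy.requested_s == pytest.approx(8 * H + 240 * 60.0)
        assert dummy.dummy

    def test_non_dialysis_no_dummy(self):
        r = req("r0", "A", "B", 8 * H)
        assert make_dummy_returns([r], stay_estimate=lambda r: 0.0) == []


class TestSimulateDay:
    def test_no_adhoc_reoptimize_equals_initial_schedule(self, tau):
        rng = random.Random(66)
        plannable = tuple(rand_requests(rng, 4, tau))
        day = TransportDay(plannable=plannable, adhoc=())
        vehicles = [veh("v0"), veh("v1")]
        res = simulate_transport_day(day, vehicles, policy="reoptimize", tau=tau)
        init = solve_vrpgtw(list(plannable), vehicles, tau=tau)
        assert res.delays == init.delays

    def test_no_infectious_on_clean_vehicle_any_policy(self, tau):
        rng = random.Random(67)
        plannable = tuple(rand_requests(rng, 4, tau, infectious_p=0.5))
        adhoc = tuple(
            req(f"a{i}", "B", "A", 13 * H + i * 600, release_s=12 * H, infectious=(i % 2 == 0))
            for i in range(2)
        )
        day = TransportDay(plannable=plannable, adhoc=adhoc)
        vehicles = [veh("v0", fleet="clean"), veh("v1", fleet="covid"), veh("v2", fleet="floater")]
        byid = {r.id: r for r in plannable + adhoc}
        for policy in ("reoptimize", "nearest_available"):
            res = simulate_transport_day(day, vehicles, policy=policy, tau=tau)
            for vid, stops in res.schedule.routes.items():
                v = next(x for x in vehicles if x.id == vid)
                for s in stops:
                    r = byid[s.request_id]
                    if v.fleet == "clean":
                        assert not r.infectious
                    if v.fleet == "covid":
                        assert r.infectious

    def test_reoptimize_beats_nearest_available(self, tau):
        rng = random.Random(68)
        for trial in range(3):
            plannable = tuple(rand_requests(rng, 4, tau))
            adhoc = tuple(
                req(
                    f"a{i}",
                    *rng.sample(["A", "B", "C", "D"], 2),
                    rng.uniform(12 * H, 15 * H),
                    release_s=11 * H,
                )
                for i in range(2)
            )
            day = TransportDay(plannable=plannable, adhoc=adhoc)
            vehicles = [veh("v0"), veh("v1")]
            opt = simulate_transport_day(day, vehicles, policy="reoptimize", tau=tau)
            naive = simulate_transport_day(day, vehicles, policy="nearest_available", tau=tau)
            assert opt.d_max <= naive.d_max + 1e-6


class TestMetrics:
    def test_empty_schedule_all_zero(self):
        sched = TransportSchedule(routes={"v0": []}, delays={})
        m = schedule_metrics(sched, vehicles=[veh()])
        assert m.d_max == 0.0 and m.total_delay == 0.0
        assert m.shift_violations == 0 and m.gantt == []

    def test_known_delays(self):
        sched = TransportSchedule(
            routes={"v0": [Stop("a", 0, 1), Stop("b", 2, 3), Stop("c", 4, 5)]},
            delays={"a": 0.0, "b": 7 * 60.0, "c": 12 * 60.0},
        )
        m = schedule_metrics(sched)
        assert m.d_max == 12 * 60.0
        assert m.total_delay == 19 * 60.0

    def test_recount_from_raw_stops(self, tau):
        rng = random.Random(69)
        requests = rand_requests(rng, 4, tau, infectious_p=0.3)
        vehicles = [veh("v0", fleet="floater"), veh("v1", fleet="floater")]
        sched = solve_vrpgtw(requests, vehicles, tau=tau)
        m = schedule_metrics(sched, vehicles=vehicles, requests=requests)
        assert m.d_max == pytest.approx(max(sched.delays.values()))
        assert m.total_delay == pytest.approx(sum(sched.delays.values()))
        assert len(m.gantt) == len(requests)
        for row in m.gantt:
            assert row.end_s > row.start_s


class TestDummyPairedSimulation:
    def test_dummies_never_worsen_realized_dmax_over_20_seeds(self):
        """Dialysis returns materialize within 20 min of their estimate; the
        paired day with dummy anticipation never realizes a larger D_max."""
        import numpy as np

        from careplan.synthgeo import (
            RegionConfig,
            TransportDayConfig,
            generate_region,
            sample_transport_day,
        )
        from careplan.transport import TravelTimes
        from careplan.geonet import SpeedProfile

        region = generate_region(
            RegionConfig(grid_nx=6, grid_ny=6, n_municipalities=3, total_population=9000),
            seed=13,
        )
        profile = SpeedProfile(speeds={"major": 80.0, "minor": 50.0})
        t = TravelTimes(region.network, profile)
        depots = list(region.depots)
        vehicles = [
            Vehicle(
                id=f"veh{k}", depot=depots[k % len(depots)],
                shift_start_s=6 * H, shift_end_s=20 * H, fleet="floater",
            )
            for k in range(2)
        ]
        stay = 4 * H
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            base = sample_transport_day(
                region,
                TransportDayConfig(
                    n_plannable=5, adhoc_rate_per_h=0.2,
                    dialysis_fraction=0.5, day_end_s=12 * H,
                ),
                seed=seed,
            )
            returns = []
            for r in base.plannable:
                if r.dialysis:
                    actual = min(r.requested_s + stay + rng.uniform(-1200, 1200), 19 * H)
                    returns.append(
                        TransportRequest(
                            id=f"{r.id}:ret", pickup=r.dropoff, dropoff=r.pickup,
                            requested_s=actual, load_s=r.load_s, unload_s=r.unload_s,
                            release_s=actual - 1800,
                        )
                    )
            adhoc = tuple(sorted(list(base.adhoc) + returns, key=lambda r: (r.release_s, r.id)))
            day = TransportDay(plannable=base.plannable, adhoc=adhoc)
            with_d = simulate_transport_day(
                day, vehicles, policy="reoptimize", tau=t, dummy_rule=lambda r: stay
            )
            without = simulate_transport_day(day, vehicles, policy="reoptimize", tau=t)
            assert with_d.d_max <= without.d_max + 1e-6
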