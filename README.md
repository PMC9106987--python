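# careplan

Optimization toolkit for ambulatory-care planning. It bundles the four
planning problems that public-health planners face across strategic,
tactical, and operational horizons, together with the street-network routing
layer they all share:

- **Vaccination-center location** (`careplan.vaxloc`) — a mixed-integer
  program deciding which candidate centers to open, assigning every
  municipality to exactly one open center, and staffing each center with
  enough physicians: minimize
  `w_c·|open| + w_d·Σ_m pop_m·dist(m, σ(m)) + w_p·Σ_s z_s`
  subject to single assignment, `z_s ≥ ⌈assigned population / throughput⌉`,
  and optional capacities, prefixed assignments and distance caps.
- **Emergency-doctor provision** (`careplan.emsplan`) — *q-Multiset
  Multicover*: place the minimum number of suppliers (doctors) at station
  locations so that every region's integral client demand can be served,
  each supplier covering up to `q` clients in incident regions; a robust
  variant requires feasibility for every demand scenario in a finite
  uncertainty set. Coverage is verified by max-flow, and an event-based
  simulator replays emergency logs under an allocation (nearest-available
  dispatch, FIFO queueing, re-dispatchable returning doctors) to produce
  median response times per municipality.
- **Out-of-hours pharmacy rostering** (`careplan.pharmshift`) — an annual
  duty plan minimizing total 24-hour services subject to coverage (`c + γ`
  distinct in-range pharmacies per municipality-day, the surplus `γ`
  absorbing quarantine closures), geographic dispersion, rest periods,
  minimum annual services, and fairness brackets around an idealized,
  lexicographically fair load vector. Includes exact aggregation of
  mathematically equivalent pharmacies and a rolling-horizon decomposition.
- **Patient-transport scheduling** (`careplan.transport`) — a vehicle
  routing problem with general time windows: patient pickups are soft
  (late, never early), driver shifts hard. The objective is lexicographic —
  minimize the maximum delay `D_max`, then the total delay — with Covid
  fleet separation, service add-ons, floater changeovers, dummy return
  transports for dialysis trips, and online re-optimization when ad-hoc
  requests arrive.
- **Street networks** (`careplan.geonet`) — OSM-style network construction
  (splitting ways at crossings, smoothing degree-2 nodes), shortest travel
  times with turn restrictions either respected (two interchangeable query
  modes) or ignored (blue-light routing), multi-source isochrone fields, and
  per-street-class speed estimation from trip logs by iterated Huber
  regression.

Because the original planning datasets are confidential, the toolkit ships a
seeded synthetic-region generator (`careplan.synthgeo`) producing street
networks, municipalities with populations, candidate sites, pharmacies,
Poisson emergency logs and daily transport request streams with the
statistical structure the planners assume.

## Worked example

```sh
careplan synth --seed 7 --grid 8 --municipalities 5 --population 40000 --out region.json
careplan ems --region region.json --seed 7 --days 2 --daily-rate 8 --out-dir ems_out
```

prints

```
allocation cost 3; events and summary in ems_out
```

meaning three emergency doctors suffice to cover every municipality's demand
within the 12-minute blue-light reachability threshold. `ems_out/ems_summary.json`
then holds the simulated per-municipality median response times for the
sampled emergency log, and `ems_out/ems_events.csv` one row per emergency
(alarm, dispatch, arrival, response seconds). Similarly:

```sh
careplan pharm --region region.json --days 14 --radius-km 8 --out-dir pharm_out
```

prints `plan with 14 services; reports in pharm_out` — a fortnight roster in
which exactly one pharmacy (rotating under rest constraints) covers all five
municipality centers each day, with zero constraint violations in the
independent validation report.

From Python:

```python
from careplan.synthgeo import RegionConfig, generate_region
from careplan.emsplan import CoverInstance, solve_qmsmc, incidence_from_travel_time
from careplan.geonet import SpeedProfile

region = generate_region(RegionConfig(grid_nx=8, grid_ny=8, n_municipalities=5), seed=7)
profile = SpeedProfile(speeds={"major": 100.0, "minor": 60.0}, vehicle_type="bluelight")
inc = incidence_from_travel_time(region, region.candidate_sites, profile)
inst = CoverInstance(
    locations=region.candidate_sites,
    regions=tuple(sorted(region.municipalities)),
    clients={m: 1 for m in region.municipalities},
    incidence=inc,
    q=2,
)
print(solve_qmsmc(inst).suppliers)   # e.g. {'n0_4': 1, 'n4_0': 1}
```

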