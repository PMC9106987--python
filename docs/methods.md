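# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic data does and does not emulate.

## Street networks and routing (`geonet`)

Networks are built from way-based raw input: ways are split at crossings
(nodes shared by two or more ways, repeated nodes, and way endpoints), and
interior degree-2 nodes joining two edges with identical attributes (street
class, one-way flag) are smoothed away with lengths summed, so total network
length is conserved exactly. Nodes referenced by a turn restriction are
never smoothed; a restriction whose flanked node pair no longer bounds a
single edge of the referenced way is rejected as unmappable rather than
silently dropped. Coordinates are planar meters; lon/lat input is projected
equirectangularly about the region centroid, which is adequate at state
scale (sub-0.1% length distortion over ~100 km).

Turn restrictions are forbidden maneuvers given as alternating node–edge
walks (at least two edges). Only forbidden maneuvers are supported;
mandatory-turn relations are out of scope. Two restriction-aware query modes
exist and must agree to 1e-9 s:

- **state** (default): Dijkstra over histories of the last `h` traversed
  arcs, where `h` is one less than the longest restriction. This is
  efficient when restrictions are few relative to the network.
- **expanded**: the same state space materialized as an explicit digraph and
  solved with networkx's Dijkstra — an independent code path kept for
  verification.

Ignoring restrictions models blue-light driving. Dijkstra ties are broken by
ascending node identifier so returned paths are reproducible. Unreachable
destinations yield an explicit infinite-duration result, never an exception.

**Speed estimation.** Per-class speeds for a vehicle type are estimated from
observed trip durations by iterating: route every trip under the current
profile, extract per-class driven meters as the design matrix, regress
durations on distances with zero intercept (a trip's duration is purely
distance-driven) using Huber IRLS (tuning constant 1.345, the conventional
95%-efficiency choice), convert coefficients (s/m) back to km/h, repeat.
Convergence is a maximum relative speed change below 1e-3, capped at 20
iterations; the best iterate is returned with a convergence flag otherwise.
Speeds are clamped to ≥ 1 km/h; classes never driven by any routed trip keep
their initial speed with a warning, as do classes whose coefficient turns
non-positive. When the robust scale estimate degenerates (near-exact fit)
the plain least-squares solution is used, since Huber weights are undefined
at zero scale.

## Synthetic regions (`synthgeo`)

The generator emulates the *structure* the planners rely on, not German
demographics: a jittered grid street network with random diagonal shortcuts
and randomly classed major/minor lines; municipalities as Voronoi cells of
random center nodes; populations from a symmetric Dirichlet(α = 2) split of
the regional total (largest-remainder rounding, each municipality ≥ 1);
neighbor sets from street-edge adjacency between cells; pharmacies placed
proportionally to population; emergency arrivals as a homogeneous Poisson
process with scenes drawn proportionally to population and log-normal
on-scene durations; transport days with plannable pickups uniform over
06:00–18:00 and Poisson ad-hoc arrivals with 10–45-minute lead times.
Everything is deterministic in (config, seed) down to the serialized bytes.

What passing tests on these regions shows: the solvers and simulators are
correct against exhaustive oracles and their guarantees (robustness,
dominance, fairness) hold under the stated stochastic structure. What they
do not show: calibration to any real region — real road topology, commuting
asymmetries, heavy-tailed demand, or data errors are not modeled.

## Vaccination centers (`vaxloc`)

Each municipality is assigned to exactly one center (no fractional splits),
distances are Euclidean between municipality centers and candidate sites —
the question is a national/state-scale comparison of scenarios, so
street-level routing would add cost without changing the comparisons.
Physician staffing is the ceiling of assigned population over campaign
throughput and is the only capacity coupling unless a scenario supplies
per-site caps. The multi-objective is a weighted sum by default
(`w_centers = 1`, `w_distance = 1e-6` per person-meter, `w_physicians =
0.1`; documented choices, since no canonical weighting exists); a
lexicographic mode (fewest centers, then distance, then physicians) serves
the "as few centers as possible" reading. Demand robustness is handled by
evaluating a plan's staffing need over a finite scenario list; full robust
optimization is out of scope. The population-weighted median distance — the
choropleth statistic — is the smallest distance whose cumulative population
reaches half the total.

## Emergency-doctor provision (`emsplan`)

*q*-Multiset Multicover is solved as a MIP with integer supplier counts and
continuous service flows; the flow polytope is integral, so continuous flows
are exact. Equal-cost optima are broken toward lexicographically smaller
location identifiers by a cost perturbation of 1e-4/|locations| — small
enough that it can never flip a unit of true cost. Feasibility of a given
allocation is decided by max-flow (source → locations at capacity
q·suppliers → incident regions → sink at client demand). The robust variant
shares supplier variables across one flow block per scenario; an explicit
finite scenario list is used because no particular uncertainty-set geometry
is canonical here (budgeted sets would slot in as additional scenario
generators). Incidence is derived from travel time: a location is incident
to a region iff the region's center is reachable within a threshold (default
12 minutes) under the blue-light profile.

The event simulator dispatches the nearest available doctor by estimated
travel time (ties: earliest idle, then identifier), queues FIFO otherwise,
and makes returning doctors re-dispatchable: a doctor interrupted mid-return
finishes the current street segment and re-routes from its end node — a
discrete approximation that avoids interpolating positions inside segments.
A dispatched doctor is never redirected mid-mission. Response time is alarm
to arrival; queue wait is alarm to dispatch. Municipalities with no
emergencies are reported as missing values, never zero.

## Pharmacy rosters (`pharmshift`)

Day granularity is one 24-hour shift per calendar day. Reachability and
vicinity use street-network meters (municipalities measured at their center
node); vicinity conflicts are symmetric, using the smaller of the two
directed distances. Rest semantics: duty on day `t` forbids days
`t+1 … t+r`. Quarantine robustness is modeled as surplus coverage — `c + γ`
distinct in-range pharmacies per municipality-day — a conservative
sufficient condition chosen over scenario enumeration because deleting any
≤ γ pharmacies then provably leaves coverage ≥ c (the tests verify this by
exhaustive subset deletion).

**Idealized fairness.** The load reference solves a simplified problem with
coverage constraints only (no vicinity, no rest — the reference should
express coverage burden, not scheduling friction). Its sorted-descending
load vector is lexicographically minimal: the heaviest burden is as small as
possible, then the next, and so on. The default method computes this exactly
by alternating two MIPs per load level — minimize the cumulative number of
pharmacies whose load reaches the level, then minimize the next lower level
— with cumulative count caps pinning finished levels; every optimum of the
final solve realizes the lexicographically minimal vector. A per-day
min-load greedy is kept as a fast heuristic for long horizons, but it does
not guarantee the lexicographic property when pharmacies share coverage
(two municipalities covered by {a,b} and {b,c} already defeat it), which is
why the exact method is the default wherever tractable (auto-switch above
1500 pharmacy-days). Fairness enters the real roster as multiplicative
brackets `⌊(1−δ)·load⌋ … ⌈(1+δ)·load⌉` around the idealized loads
(δ = 0.2 by default); with δ = 0 equivalent pharmacies end within one
service of each other.

**Aggregation.** Pharmacies are equivalent when municipality, covered set,
and vicinity-conflict structure coincide (computed by color refinement).
The aggregated model uses integer open-counts per class-day; the rest
constraint becomes a sliding-window capacity (any `r+1` consecutive days
admit at most `multiplicity` services per class), which is exact:
chronological round-robin disaggregation always yields a feasible
member-level plan of equal total, and balances member counts to within one —
so the minimum-services and fairness totals aggregate exactly when member
brackets coincide (conservatively otherwise). The aggregated route is exact
without fairness brackets and is tested as such.

**Rolling horizon** (defaults: 28-day windows, 7-day overlap) commits each
window's first `W−O` days, carries rest constraints and cumulative service
counts across boundaries, and spreads the annual minimum by requiring only
what the remaining capacity `⌈days left/(r+1)⌉` cannot absorb. A window
infeasible with fairness brackets is retried without them before failing;
the committed plan always satisfies every full-horizon constraint, at a
total that may exceed the exact optimum.

`validate_plan` re-checks every family with naive double loops, sharing no
code with the solvers, and computes the fairness-chart statistics
(within-municipality maximum difference, per-pharmacy difference to the
municipality average).

## Patient transport (`transport`)

Delays are one-sided: vehicles wait at a pickup until the requested time,
never serve early, and lateness is unbounded by default (a cap option
exists, off by default). The lexicographic objective is realized as two
sequential solves — minimize `D_max`, then fix it (with slack 1e-7 + 1e-9
relative, solver round-off only) and minimize total delay — rather than a
weighted blend, which would require an arbitrary constant. Vehicle capacity
is one patient; pooling is out of scope. Sequencing uses continuous start
times with big-M constraints over all same-vehicle request pairs, which is
valid because shortest-path travel times are metric; `M` is the shift
horizon plus twice the largest service-plus-travel link. The covid service
add-on applies to infectious stops; floater changeover (default equal to
the add-on, as neither is quantified independently) applies when
consecutive stops switch infection category.

Re-optimization fixes started and finished stops, anchors each vehicle at
the dropoff of its last committed stop (available from its end time), and
re-solves everything outstanding; an infeasible new request is flagged
unserved instead of failing the day. Dummy returns for dialysis trips swap
origin and destination at the outward time plus an estimated stay and are
replaced (matched by origin–destination) when the actual return
materializes. The nearest-available baseline dispatches the closest idle
compatible vehicle at the moment a transport is due (ties: earliest idle,
then identifier), queues FIFO, and never plans ahead; shift violations it
incurs are counted, not prevented.

## Solver and sizes

All MIPs go through `scipy.optimize.milp` (HiGHS) with relative and
absolute gaps of 1e-9, so "optimal" in the tests means proven optimal at
solver tolerance. The exhaustive oracles bound their own scales: covering
instances up to 5×5 with demands ≤ 3, rosters up to 24 pharmacy-days
(vectorized enumeration of all 2^(P·T) plans), routing instances of 4
requests × 2 vehicles (assignment × permutation enumeration), and toy
graphs of ≤ 12-edge paths. Simulation comparisons use 8×8-grid regions,
5 plannable transports with ~3 ad-hoc per day over 20 paired seeded days,
and 60 emergencies/day for dominance checks — sizes at which every
randomized suite completes in seconds while exercising all constraint
interactions.

## Known limitations

- Mandatory-turn restrictions and OSM PBF ingestion are not supported; no
  routing speed-up structures (the networks of interest fit plain Dijkstra).
- The equirectangular projection is unsuitable far from the region centroid.
- Aggregated rostering with fairness brackets is conservative when members
  of an equivalence class carry idealized loads differing by one.
- The transport MIP's big-M formulation scales to tens of requests per
  solve, not hundreds; real deployments would need a column-generation or
  insertion-heuristic layer on top.
- The simulators assume deterministic travel times; stochastic durations
  and mid-mission redirection are not modeled.
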