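"""Street-class speed estimation from observed trip durations.

Blue-light vehicles do not drive at ordinary car speeds, so per-class speeds
are estimated from historical operations: route every trip under the current
profile, extract the per-class driven distances, regress the observed
durations on those distances with a robust loss (the coefficients are inverse
speeds), update the profile, and repeat until the profile stabilizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from careplan.geonet.network import StreetNetwork
from careplan.geonet.routing import SpeedProfile, shortest_time

#: Huber tuning constant, the conventional 95%-efficiency choice
HUBER_T = 1.345
MIN_SPEED_KMH = 1.0


@dataclass(frozen=True)
class TripRecord:
    origin: str
    dest: str
    duration_s: float

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("trip duration must be positive")
        if self.origin == self.dest:
            raise ValueError("trip origin and destination must differ")


@dataclass
class SpeedEstimationResult:
    profile: SpeedProfile
    converged: bool
    iterations: int
    excluded_classes: tuple[str, ...] = field(default=())


def _class_distances(net: StreetNetwork, profile: SpeedProfile, trips, classes, respect_restrictions):
    """Design matrix: per-trip driven meters on each street class under the
    routes induced by ``profile``; rows for unreachable trips are dropped."""
    idx = {c: j for j, c in enumerate(classes)}
    rows, y = [], []
    for t in trips:
        res = shortest_time(net, profile, t.origin, t.dest, respect_restrictions=respect_restrictions)
        if not res.reachable:
            warnings.warn(f"trip {t.origin}->{t.dest} unreachable; skipped")
            continue
        row = np.zeros(len(classes))
        for eid in res.path:
            e = net.edges[eid]
            row[idx[e.cls]] += e.length_m
        rows.append(row)
        y.append(t.duration_s)
    return np.asarray(rows), np.asarray(y)


def _robust_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Zero-intercept robust regression of duration on class distances.

    Falls back to the plain least-squares solution when the fit is (near)
    exact, where the MAD scale underlying the Huber weights degenerates.
    """
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    scale = np.median(np.abs(resid)) / 0.6745 if len(resid) else 0.0
    if scale < 1e-9 * max(1.0, float(np.mean(np.abs(y)))):
        return beta_ols
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T))
    return np.asarray(rlm.fit().params)


def estimate_speed_profile(
    net: StreetNetwork,
    initial: SpeedProfile,
    trips,
    tol: float = 1e-3,
    max_iter: int = 20,
    respect_restrictions: bool = False,
) -> SpeedEstimationResult:
    """Iterated robust-regression estimate of per-class speeds (km/h).

    Convergence: maximum relative speed change below ``tol``.  Classes never
    driven by any routed trip keep their initial speed (with a warning).
    Returned speeds are clamped to >= 1 km/h.
    """
    classes = sorted(net.street_classes())
    speeds = dict(initial.speeds)
    trips = list(trips)
    excluded: set[str] = set()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        profile = SpeedProfile(speeds=dict(speeds), vehicle_type=initial.vehicle_type)
        X, y = _class_distances(net, profile, trips, classes, respect_restrictions)
        if X.size == 0:
            warnings.warn("no routable trips; returning initial profile")
            return SpeedEstimationResult(profile, False, it, tuple(sorted(classes)))
        driven = X.sum(axis=0) > 0
        active = [c for c, d in zip(classes, driven) if d]
        for c, d in zip(classes, driven):
            if not d and c not in excluded:
                excluded.add(c)
                warnings.warn(f"street class {c!r} never driven; keeping initial speed")
        beta = _robust_fit(X[:, driven], y)
        new_speeds = dict(speeds)
        for c, b in zip(active, beta):
            if b > 1e-12:
                new_speeds[c] = max(MIN_SPEED_KMH, 3.6 / b)  # s/m -> km/h
            else:
                warnings.warn(f"non-positive coefficient for class {c!r}; keeping previous speed")
        delta = max(abs(new_speeds[c] - speeds[c]) / speeds[c] for c in classes)
        speeds = new_speeds
        if delta < tol:
            converged = True
            break
    return SpeedEstimationResult(
        profile=SpeedProfile(speeds=speeds, vehicle_type=initial.vehicle_type),
        converged=converged,
        iterations=it,
        excluded_classes=tuple(sorted(excluded)),
    )
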