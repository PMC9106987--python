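"""Domain types for patient-transport scheduling."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from careplan.errors import InputError


@dataclass(frozen=True)
class TransportRequest:
    """One patient transport: pickup -> dropoff at a requested time.

    The requested pickup time is a soft window: the pickup may start later
    (the delay is what schedules minimize) but never earlier.  ``release_s``
    is when the request becomes known to the dispatcher (equals 0 / day
    start for plannable requests, later for ad-hoc ones).
    """

    id: str
    pickup: str
    dropoff: str
    requested_s: float  # seconds since midnight, soft
    load_s: float = 300.0
    unload_s: float = 300.0
    infectious: bool = False
    dialysis: bool = False
    release_s: float = 0.0
    dummy: bool = False  # placeholder return trip, replaceable on materialization

    def __post_init__(self):
        if self.pickup == self.dropoff:
            raise InputError(f"request {self.id}: pickup equals dropoff")
        if self.load_s < 0 or self.unload_s < 0:
            raise InputError(f"request {self.id}: negative service duration")
        if self.release_s > self.requested_s:
            raise InputError(f"request {self.id}: released after requested time")


FLEET_TYPES = ("clean", "covid", "floater")


@dataclass(frozen=True)
class Vehicle:
    id: str
    depot: str
    shift_start_s: float
    shift_end_s: float
    fleet: str = "clean"
    covid_addon_s: float = 600.0  # protective clothing + disinfection per infectious stop
    changeover_s: float = 600.0  # floater switching between infection categories

    def __post_init__(self):
        if not self.shift_start_s < self.shift_end_s:
            raise InputError(f"vehicle {self.id}: shift start must precede end")
        if self.fleet not in FLEET_TYPES:
            raise InputError(f"vehicle {self.id}: unknown fleet type {self.fleet!r}")

    def can_serve(self, req: TransportRequest) -> bool:
        if self.fleet == "floater":
            return True
        return self.fleet == ("covid" if req.infectious else "clean")


@dataclass(frozen=True)
class Stop:
    """A served request on a vehicle's route: pickup start through dropoff end."""

    request_id: str
    pickup_start_s: float
    dropoff_end_s: float
    executed: bool = False  # already started/finished; immutable in re-optimization


@dataclass
class TransportSchedule:
    """Per-vehicle ordered stop sequences plus per-request delays."""

    routes: dict[str, list[Stop]]  # vehicle id -> stops in service order
    delays: dict[str, float]  # request id -> max(0, pickup start - requested)
    d_max: float = 0.0
    total_delay: float = 0.0
    unserved: tuple[str, ...] = ()

    def request_vehicle(self) -> dict[str, str]:
        out = {}
        for vid, stops in self.routes.items():
            for s in stops:
                out[s.request_id] = vid
        return out


@dataclass
class DayState:
    """Mid-day snapshot used by online re-optimization: what already happened
    (immutable) and what is still outstanding."""

    now_s: float
    executed: dict[str, list[Stop]]  # vehicle -> executed stop prefix
    positions: dict[str, tuple[str, float]]  # vehicle -> (node, available-from time)
    outstanding: list[TransportRequest] = field(default_factory=list)

    def validate(self):
        for vid, stops in self.executed.items():
            for s in stops:
                if s.pickup_start_s > self.now_s:
                    raise InputError(f"executed stop {s.request_id} starts after 'now'")


def clone_replacing(req: TransportRequest, **kw) -> TransportRequest:
    return replace(req, **kw)
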