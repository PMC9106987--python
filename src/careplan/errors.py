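"""Exception types shared across the toolkit."""


class CareplanError(Exception):
    """Base class for all toolkit errors."""


class InputError(CareplanError):
    """Malformed or inconsistent input data (dangling references, bad config)."""


class ConfigurationError(CareplanError):
    """A run-time configuration is incomplete (e.g. a street class without a speed)."""


class InfeasibleError(CareplanError):
    """An optimization model has no feasible solution.

    Carries a structured ``report`` naming the constraint families and
    units (municipalities, regions, requests, ...) involved, so callers can
    surface an actionable diagnosis instead of a bare solver status.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report if report is not None else {}
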