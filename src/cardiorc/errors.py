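"""Exception hierarchy."""


class CardioRCError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(CardioRCError, ValueError):
    """Invalid exercise protocol or query outside its time range."""


class FitError(CardioRCError, RuntimeError):
    """Step-response identification failed (degenerate input or no convergence)."""


class InfeasibleCircuitError(CardioRCError, ValueError):
    """Requested kinetic coefficients do not map to a realizable RC circuit."""


class ScheduleError(CardioRCError, ValueError):
    """Malformed switch schedule (gap, overlap, or wrong origin)."""


class SeriesError(CardioRCError, ValueError):
    """Malformed time series (bad CSV, non-monotone time base, length mismatch)."""
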