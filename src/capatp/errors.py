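"""Exception types raised by the transport solvers and geometry builders."""


class CapatpError(Exception):
    """Base class for all package errors."""


class GeometryError(CapatpError):
    """Invalid vessel layout (overlap, out-of-box placement, bad ids)."""


class DomainError(CapatpError, ValueError):
    """Physical argument outside its admissible domain (e.g. negative PO2)."""


class StabilityError(CapatpError):
    """An explicit pseudo-time update produced NaN or an out-of-range state."""

    def __init__(self, message, dt=None, location=None):
        super().__init__(message)
        self.dt = dt
        self.location = location


class ConvergenceError(CapatpError):
    """Steady-state iteration hit its iteration budget before the tolerances.

    Carries the residual history so the caller can inspect the trace.
    """

    def __init__(self, message, residual_log=None):
        super().__init__(message)
        self.residual_log = residual_log or []
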