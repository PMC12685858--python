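"""Exception hierarchy for emboflow."""


class EmboflowError(Exception):
    """Base class for all emboflow errors."""


class TreeValidationError(EmboflowError, ValueError):
    """A vascular tree violates a structural invariant (cycle, multiple
    roots, nonpositive radius, missing segment, ...)."""


class ConfigurationError(EmboflowError, ValueError):
    """A generator or boundary-condition configuration is infeasible."""


class SolverError(EmboflowError, RuntimeError):
    """The network flow solve failed (singular or degenerate system)."""


class CalibrationError(EmboflowError, RuntimeError):
    """Stall-pressure calibration could not bracket the requested value."""


class BracketError(EmboflowError, RuntimeError):
    """A 1-D root search failed to bracket its root."""
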