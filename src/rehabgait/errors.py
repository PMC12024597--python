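"""Exception hierarchy for rehabgait.

All toolkit-specific failures derive from :class:`RehabGaitError` so callers
can catch one base class at API boundaries (the CLI maps them to exit code 1).
"""


class RehabGaitError(Exception):
    """Base class for all rehabgait errors."""


class StructuralError(RehabGaitError):
    """Network topology violates a structural invariant (cycle, layer, role)."""


class FixtureError(RehabGaitError):
    """A packaged or user-supplied fixture is missing, malformed, or invalid."""


class ParseError(FixtureError):
    """A file failed to parse; carries the offending line number when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InconsistentEvidenceError(RehabGaitError):
    """Evidence assigns probability zero to every joint configuration."""


class CapacityError(RehabGaitError):
    """Exact enumeration was requested on a state space that is too large."""


class ConfigError(RehabGaitError):
    """An option value is outside its documented domain."""


class DegenerateEstimateError(RehabGaitError):
    """A transition matrix cannot be estimated (empty window, no smoothing)."""


class KinematicsError(RehabGaitError):
    """Base class for mechanism-side failures."""


class InfeasiblePoseError(KinematicsError):
    """Requested pose or actuator lengths are outside the reachable set."""


class SingularGeometryError(KinematicsError):
    """Geometry makes the closed-form solution degenerate (e.g. m = 0)."""


class CapabilityError(KinematicsError):
    """Operation requires full link dimensions but only lumped offsets exist."""


class CalibrationError(KinematicsError):
    """Calibration rows cannot be reconciled with the length model."""
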