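"""Exception hierarchy for spindlefit.

Every failure mode surfaced by the pipeline derives from :class:`SpindleError`
so callers can catch the package's errors in one clause.  The CLI maps
``InvalidInput``-family errors to exit code 2 and numerical failures to 3.
"""


class SpindleError(Exception):
    """Base class for all spindlefit errors."""


class InvalidInput(SpindleError, ValueError):
    """Malformed or out-of-contract input (bad shapes, unsorted spikes, ...)."""


class ConfigurationError(SpindleError, ValueError):
    """A model/config combination that cannot be interpreted."""


class DegenerateTarget(SpindleError, ValueError):
    """Target series with zero variance: SSM-normalised costs are undefined."""


class SmallSampleError(SpindleError, ValueError):
    """AICc undefined because n <= k + 1 for the finite-sample correction."""


class InfeasibleProtocol(SpindleError, ValueError):
    """Stretch kinematics that cannot be realised (velocity unreachable)."""


class FitFailure(SpindleError, RuntimeError):
    """Optimizer failed to produce a finite solution at every lag."""


class IntegrationFailure(SpindleError, RuntimeError):
    """Force simulation produced a non-finite state."""
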