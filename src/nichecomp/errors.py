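"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`ValidationError` (and subclasses)
exit with status 2; runtime failures such as :class:`IntegrationError` exit 3.
"""


class NicheCompError(Exception):
    """Base class for all package errors."""


class ValidationError(NicheCompError, ValueError):
    """Invalid parameters, state, or configuration."""


class DegenerateParametersError(ValidationError):
    """Parameter combination makes a computation singular (e.g. nullcline system)."""


class DegenerateDiscretizationError(ValidationError):
    """A nonzero density rounds to zero occupants on the requested lattice."""


class IntegrationError(NicheCompError, RuntimeError):
    """ODE integration failed; carries the time at which it failed."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail
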