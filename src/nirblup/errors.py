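"""Exception hierarchy shared by all stages.

The CLI maps these onto exit codes: configuration problems (2), data
problems (3), convergence failures (4).
"""


class NirblupError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NirblupError):
    """A run or simulation configuration is invalid."""


class DataError(NirblupError):
    """Input data violate a structural precondition (ids, missingness, design)."""


class ComputationError(NirblupError):
    """A numerical operation cannot be completed (singular systems, non-finite input)."""


class ConvergenceError(ComputationError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
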