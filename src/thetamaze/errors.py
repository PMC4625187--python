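"""Exception hierarchy for the thetamaze pipeline.

Every stage raises a subclass of :class:`ThetamazeError` so callers (and the
CLI) can distinguish configuration problems (exit code 2) from data problems
(exit code 3).
"""


class ThetamazeError(Exception):
    """Base class for all package errors."""


class ParameterError(ThetamazeError, ValueError):
    """An argument is outside its valid domain (e.g. f0 beyond Nyquist)."""


class ConfigurationError(ThetamazeError, ValueError):
    """A simulation/analysis configuration is internally inconsistent."""


class SchemaError(ThetamazeError, ValueError):
    """An input table or recording violates the expected schema."""


class DesignError(ThetamazeError, ValueError):
    """A statistical design is incomplete or unbalanced."""


class InsufficientDataError(ThetamazeError, ValueError):
    """Not enough epochs/points to compute the requested quantity."""


class AllEpochsRejectedError(InsufficientDataError):
    """Artifact rejection removed every epoch of a recording."""


class DegenerateDataError(ThetamazeError, ValueError):
    """Data admit no defined answer (zero variance, identical pairs...)."""


class ZeroPowerError(DegenerateDataError):
    """A channel has zero total band power, so relative power is undefined."""
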