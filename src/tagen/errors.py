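"""Exception hierarchy shared across the package.

All errors derive from :class:`TagenError` so callers can catch the package's
failures with one handler; the subclasses distinguish bad parameters from
degenerate data so tests can assert on the precise failure mode.
"""


class TagenError(Exception):
    """Base class for all package errors."""


class ParameterError(TagenError, ValueError):
    """A numeric parameter is non-finite or outside its admissible range."""


class ConfigurationError(TagenError, ValueError):
    """A combination of parameters is inconsistent (each may be valid alone)."""


class InsufficientDataError(TagenError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(TagenError, ValueError):
    """The statistic is undefined on this input (zero mean, zero median, ...)."""


class DegenerateTestError(TagenError, ValueError):
    """A test statistic cannot be formed (zero variance in a denominator, ...)."""


class IdentifierError(TagenError, KeyError):
    """Requested identifiers are absent from the data universe."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = list(missing)

    def __str__(self) -> str:  # KeyError would repr() the message otherwise
        return self.args[0]


class GeometryError(TagenError, ValueError):
    """Image shapes or region coordinates are inconsistent or out of bounds."""


class ProtocolError(TagenError, RuntimeError):
    """An analysis step was invoked out of its required order (e.g. ungated events)."""


class DataError(TagenError, ValueError):
    """Input data violate a structural requirement (empty population, ...)."""
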