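"""Exception hierarchy for the frcc package."""


class FrccError(Exception):
    """Base class for all package-specific errors."""


class ShortSignalError(FrccError, ValueError):
    """Signal shorter than one analysis frame."""


class DegenerateOrderError(FrccError, ValueError):
    """Fractional order at which the fractional frequency axis collapses."""


class SingularScatterError(FrccError, ValueError):
    """Within-class scatter matrix singular even after regularization."""


class DegenerateClassesError(FrccError, ValueError):
    """Class means coincide; no discriminant direction exists."""


class InsufficientDataError(FrccError, ValueError):
    """Not enough samples to fit the requested model."""


class UndefinedRateError(FrccError, ValueError):
    """Confusion-table rate with an empty denominator."""


class DegenerateDenominatorError(FrccError, ValueError):
    """Variance ratio with a zero denominator."""


class UnsupportedFormatError(FrccError, ValueError):
    """Audio file in a format the reader does not handle."""


class ConfigMismatchError(FrccError, ValueError):
    """Artifacts produced under incompatible configurations."""
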