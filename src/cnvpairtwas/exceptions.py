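"""Exception hierarchy shared across the package."""


class CnvPairTwasError(Exception):
    """Base class for all package errors."""


class ParameterError(CnvPairTwasError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(CnvPairTwasError, ValueError):
    """Input is formally valid but carries no usable variation (e.g. a
    constant vector handed to a rank transform)."""


class AlignmentError(CnvPairTwasError, ValueError):
    """Two inputs that must share an index (samples, variants) do not."""


class CatalogError(CnvPairTwasError, KeyError):
    """A gene or region identifier is unknown to the catalog."""


class DependencyError(CnvPairTwasError, RuntimeError):
    """A pipeline stage was requested before its upstream artifacts exist."""


class NumericalInputError(CnvPairTwasError, ValueError):
    """A numerical input violates a structural requirement (e.g. a
    correlation matrix that is not positive semi-definite)."""
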