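"""Exception types shared across the package."""


class ExtractOptError(Exception):
    """Base class for all package errors."""


class ParseError(ExtractOptError, ValueError):
    """A design-table file could not be parsed; message names row/column."""


class SingularDesignError(ExtractOptError, ValueError):
    """The model matrix is rank deficient."""


class DegenerateLeverageError(ExtractOptError, ValueError):
    """A leverage of 1 makes leave-one-out prediction undefined."""


class DimensionError(ExtractOptError, ValueError):
    """Vector lengths are inconsistent with the declared topology."""


class TrainingError(ExtractOptError, RuntimeError):
    """Training diverged (non-finite loss); message names the epoch."""
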