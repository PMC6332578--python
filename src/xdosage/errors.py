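"""Exception types shared across the package."""


class XDosageError(Exception):
    """Base class for all package-specific errors."""


class MatrixParseError(XDosageError, ValueError):
    """A numeric field in an expression table failed to parse or is out of domain."""


class ValidationError(XDosageError, ValueError):
    """An input table violates a structural invariant (duplicates, missing columns...)."""


class DegenerateInputError(XDosageError, ValueError):
    """A statistic is undefined for the given input (zero median, empty gene set...)."""
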