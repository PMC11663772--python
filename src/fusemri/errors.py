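"""Exception hierarchy.

``ValidationError`` subclasses map to CLI exit code 2, ``NumericalError``
subclasses to exit code 3.
"""


class FusemriError(Exception):
    """Base class for package errors."""


class ValidationError(FusemriError):
    """Invalid inputs, schemas or parameters."""


class SchemaError(ValidationError):
    """A table is missing columns or violates the expected layout."""


class ParameterError(ValidationError):
    """A configuration value is out of its admissible range."""


class UndefinedChangeError(ValidationError):
    """Relative symptom change requested for a zero baseline score."""


class DegenerateSeriesError(ValidationError):
    """A time series is constant where variability is required."""


class NumericalError(FusemriError):
    """A numerical routine failed to produce a usable result."""


class SingleClassError(NumericalError):
    """A training set contains only one class."""
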