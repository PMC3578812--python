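"""Exception hierarchy for sivar."""


class SivarError(Exception):
    """Base class for all sivar errors."""


class ConfigurationError(SivarError):
    """A configuration value is missing or out of range (names the field)."""


class ValidationError(SivarError):
    """Input data violate a structural precondition."""


class NotFittedError(SivarError):
    """An operation requires a fitted model."""


class FittingError(SivarError):
    """Model estimation could not be carried out."""


class AggregationError(SivarError):
    """An aggregate was requested over an empty collection."""
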