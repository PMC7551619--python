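"""Exception hierarchy shared across the package."""


class ThreshpanelError(Exception):
    """Base class for all package errors."""


class SchemaError(ThreshpanelError):
    """A required column is missing or the file layout is wrong."""


class IntegrityError(ThreshpanelError):
    """A dataset violates a structural invariant (duplicate or missing
    levels for a panelist, outcome vector of the wrong length, ...)."""


class DomainError(ThreshpanelError):
    """A value is outside its scientific domain (non-positive
    concentration, probability outside (0, 1), unknown choice token)."""


class InsufficientDataError(ThreshpanelError):
    """Not enough observations for the requested statistic."""


class UndefinedThresholdError(ThreshpanelError):
    """The fitted line cannot be inverted at the criterion
    (non-positive slope)."""
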