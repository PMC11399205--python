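"""Exception hierarchy for uqtriage.

All package-specific errors derive from :class:`UQTriageError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class UQTriageError(Exception):
    """Base class for all uqtriage errors."""


class ConfigurationError(UQTriageError, ValueError):
    """A configuration object violates its invariants.

    The message names the offending field.
    """


class DomainError(UQTriageError, ValueError):
    """An operation received an argument outside its mathematical domain."""


class DegenerateGroupError(DomainError):
    """A discrimination metric was requested for a single-class group."""


class SchemaError(UQTriageError, ValueError):
    """A cohort file violates the expected schema or value ranges."""


class CohortParseError(SchemaError):
    """A cohort file row could not be parsed; the message cites the row."""


class ThresholdLookupError(UQTriageError, KeyError):
    """A percentile was requested that is not present in a ThresholdSet."""
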