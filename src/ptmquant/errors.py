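"""Exception hierarchy shared across the pipeline."""


class PtmQuantError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PtmQuantError):
    """A table file does not conform to its declared dialect."""


class ParameterError(PtmQuantError, ValueError):
    """An argument is outside its admissible range."""


class DesignError(PtmQuantError):
    """The sample design is inconsistent with the requested operation."""


class DataError(PtmQuantError):
    """Input data violate a structural precondition (malformed windows, joins)."""


class ScaleError(PtmQuantError):
    """An operation was applied on the wrong intensity scale."""


class UndefinedResultError(PtmQuantError):
    """The requested statistic is undefined for this input (e.g. constant vector)."""
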