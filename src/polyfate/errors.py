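"""Exception hierarchy for the polyfate pipeline."""


class PolyfateError(Exception):
    """Base class for all polyfate errors."""


class FormatError(PolyfateError):
    """A file violates the expected on-disk format (missing/duplicate ids)."""


class StateError(PolyfateError):
    """An operation was applied to data in the wrong state (e.g. double log)."""


class MissingGeneError(PolyfateError, KeyError):
    """A requested gene identifier is absent from the expression matrix."""


class DegenerateLabelsError(PolyfateError):
    """Death-probability labeling is undefined (all combined markers zero)."""


class UndefinedCorrelationError(PolyfateError):
    """Spearman correlation is undefined (a constant input vector)."""


class ParameterError(PolyfateError, ValueError):
    """An argument is outside its documented domain."""


class ConfigError(PolyfateError):
    """A configuration file or mapping fails validation."""
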