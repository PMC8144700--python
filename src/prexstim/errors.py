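"""Exception hierarchy.

Every error raised by this package derives from :class:`PrexstimError`, so
callers (and the CLI) can distinguish validation failures from genuine bugs.
"""


class PrexstimError(Exception):
    """Base class for all package errors."""


class MontageError(PrexstimError):
    """A required 10-20 electrode is missing or unknown."""


class FormatError(PrexstimError):
    """A file could not be parsed in the expected format."""


class ParameterError(PrexstimError):
    """An argument is outside its valid range."""


class ProtocolError(PrexstimError):
    """The activation-protocol events are incomplete or inconsistent."""


class VocabularyError(ProtocolError):
    """An event label is not a known protocol condition."""


class OverlapError(ProtocolError):
    """Protocol condition intervals overlap or are duplicated."""


class DegenerateBaselineError(PrexstimError):
    """The Rest #1 baseline power is zero or negative for some cell."""


class ClassError(PrexstimError):
    """A classifier fit received fewer than two classes."""


class ConditioningError(PrexstimError):
    """A covariance matrix is singular and no ridge was requested."""


class SeparationError(PrexstimError):
    """Logistic-regression data are perfectly separated; the MLE diverges."""


class InputError(PrexstimError):
    """Generic invalid input (shape mismatch, non-finite values...)."""


class ConfigError(PrexstimError):
    """A configuration file or object is invalid."""
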