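"""Exception hierarchy.

Everything raised on purpose derives from :class:`MosqOpenError` so callers
can catch toolkit failures with a single except clause; argument-validation
errors additionally derive from :class:`ValueError`.
"""


class MosqOpenError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(MosqOpenError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class InvalidSpecError(InvalidArgumentError):
    """A synthetic-data specification violates its invariants."""


class ModelBuildError(MosqOpenError):
    """An open-set model could not be built from the given records."""


class DegenerateTailError(ModelBuildError):
    """The distance tail carries no information (all values equal or nonpositive)."""


class ConfigError(MosqOpenError):
    """A configuration file or object is invalid."""
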