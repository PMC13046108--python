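"""Exception hierarchy."""


class InkdoseError(Exception):
    """Base class for all package errors."""


class IntegrityError(InkdoseError):
    """Packaged reference data failed an internal consistency check."""


class DomainError(InkdoseError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class CompositionError(InkdoseError):
    """A material composition cannot be closed to unit mass."""


class GeometryError(InkdoseError):
    """Phantom geometry constraints violated."""


class ConfigurationError(InkdoseError):
    """A run configuration is invalid (detected before any sampling)."""


class UndefinedDEFError(InkdoseError):
    """DEF is undefined because the control dose vanishes in a bin."""
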