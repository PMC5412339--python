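"""Exception hierarchy.

Every error raised by the library derives from :class:`NhejscopeError` so
callers (and the CLI) can catch one type at the pipeline boundary.
"""


class NhejscopeError(Exception):
    """Base class for all nhejscope errors."""


class SequenceError(NhejscopeError):
    """Malformed or empty sequence input."""


class MalformedOligoError(NhejscopeError):
    """Cloning oligo does not carry the expected BsmBI overhang structure."""


class OligoValidationError(NhejscopeError):
    """Bottom oligo inconsistent with the protospacer under every accepted
    orientation; the message carries the per-orientation diagnostics."""


class TargetNotFoundError(NhejscopeError):
    """Protospacer or primer has no exact match in the reference."""


class AmbiguousTargetError(NhejscopeError):
    """More than one protospacer site or PCR product; matches are listed."""


class OrientationError(NhejscopeError):
    """Reverse-primer match lies upstream of the forward-primer match."""


class FeatureError(NhejscopeError):
    """Feature annotation out of bounds or of the wrong shape."""


class ConfigError(NhejscopeError):
    """Invalid run configuration (missing path, bad parameter)."""


class TableError(NhejscopeError):
    """Ct or densitometry table violates its schema."""


class StatisticsError(NhejscopeError):
    """Degenerate input to a statistical routine (e.g. undefined F)."""


class SimulationError(NhejscopeError):
    """Synthetic-data generation could not satisfy its constraints."""
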