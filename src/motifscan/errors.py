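"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 1, everything else -> 2.
"""


class MotifScanError(Exception):
    """Base class for all package errors."""


class FormatError(MotifScanError):
    """A file does not conform to its declared format."""


class ConfigError(MotifScanError):
    """Invalid configuration or invalid operation parameters."""


class BoundsError(MotifScanError):
    """A span or index lies outside the object it addresses."""


class NotFoundError(MotifScanError):
    """A uniquely expected item was not found."""


class AmbiguityError(MotifScanError):
    """A query expected to resolve uniquely matched several positions."""


class ValidationError(MotifScanError):
    """A parsed value violates its documented invariant."""


class RunError(MotifScanError):
    """A prediction-run directory is incomplete or inconsistent."""


class GeometryError(MotifScanError):
    """Degenerate or mismatched coordinate input."""


class ConsistencyError(MotifScanError):
    """Cross-object bookkeeping violated (e.g. contacts outside a fragment)."""


class ConstructionError(MotifScanError):
    """A synthetic fixture cannot be realised under its constraints."""
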