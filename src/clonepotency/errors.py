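"""Exception hierarchy shared across the package."""


class ClonePotencyError(Exception):
    """Base class for all package errors."""


class SchemaError(ClonePotencyError):
    """A table is missing mandatory columns or has an unusable header."""


class ValidationError(ClonePotencyError):
    """Row-level content violates an invariant (negative count, bad enum...).

    Carries ``rows``: the offending 0-based data-row indices, when known.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class InsufficientDataError(ClonePotencyError):
    """Too few observations to compute the requested statistic."""


class ConfigError(ClonePotencyError):
    """Pipeline configuration is inconsistent or incomplete."""
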