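"""Exception hierarchy shared across the package."""


class CarbonReplaceError(Exception):
    """Base class for all package errors."""


class SchemaError(CarbonReplaceError):
    """A table is missing required columns or has wrong dtypes."""


class IntegrityError(CarbonReplaceError):
    """Values violate a cross-row invariant (e.g. condition proportions)."""


class DataError(CarbonReplaceError):
    """A physically impossible value (negative carbon, bad interval)."""


class ConfigError(CarbonReplaceError):
    """Invalid generator or pipeline configuration."""
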