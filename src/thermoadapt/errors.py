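"""Named exception types shared across the package.

Every reader and model entry point raises one of these (never a bare
ValueError) so callers can distinguish malformed input from misuse.
"""


class ThermoadaptError(Exception):
    """Base class for all package errors."""


class SchemaError(ThermoadaptError):
    """A file or table violates its declared schema (missing column,
    duplicate key, out-of-range count)."""


class TableParseError(ThermoadaptError):
    """A cell could not be parsed; the message names the row."""


class ConfigError(ThermoadaptError):
    """A run configuration contains unknown keys or invalid values."""


class ModelError(ThermoadaptError):
    """A model cannot be fitted or tested as requested (non-nested
    comparison, inestimable contrast, zero residual df, ...)."""


class SubsetError(ThermoadaptError):
    """A data subset does not contain the populations an analysis needs."""


class MitotypeError(ThermoadaptError):
    """Mitotype structure is inconsistent (e.g. shared-SNP carrier sets
    overlap partially, which would imply recombination)."""
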