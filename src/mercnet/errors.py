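"""Exception hierarchy shared across the package."""


class MercnetError(Exception):
    """Base class for all package errors."""


class FormatError(MercnetError):
    """A table on disk violates the expected format (negative counts, duplicate IDs...)."""


class AlignmentError(MercnetError):
    """Count table, metadata and taxonomy cannot be aligned (empty sample intersection)."""


class ConfigurationError(MercnetError):
    """Invalid design, effect or pipeline configuration."""


class RarefactionError(MercnetError):
    """A sample has fewer reads than the requested rarefaction depth."""


class InsufficientDataError(MercnetError):
    """Too few samples (or degenerate data) for the requested statistic."""
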