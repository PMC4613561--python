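"""Exception hierarchy shared across the pipeline."""


class ThyrometError(Exception):
    """Base class for all package errors."""


class ValidationError(ThyrometError):
    """Invalid argument or configuration value."""


class ConfigurationError(ThyrometError):
    """Inconsistent configuration (e.g. effect naming an unknown metabolite)."""


class CoverageError(ThyrometError):
    """A spectrum does not cover the requested chemical-shift range."""


class NormalizationError(ThyrometError):
    """Row normalization impossible (zero/negative total integral)."""


class SchemaError(ThyrometError):
    """Input table/model schema mismatch (variables, species names)."""


class RankError(ThyrometError):
    """Requested more latent components than the data can support."""
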