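"""Exception hierarchy shared across the pipeline stages."""


class RadhubError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RadhubError, ValueError):
    """Invalid configuration values (counts, fractions, intervals)."""


class ValidationError(RadhubError, ValueError):
    """Malformed input data (matrices, metadata, catalog files)."""


class DegenerateTopologyError(RadhubError):
    """Scale-free fit undefined: degenerate connectivity distribution.

    Raised when fewer than three non-empty connectivity bins exist or when
    all genes have identical connectivity; distinct from a merely low R^2.
    """


class TermNotSharedError(RadhubError):
    """A term is enriched in fewer than two result lists, so no cross-network
    average fold enrichment is defined for it."""
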