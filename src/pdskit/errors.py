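"""Exception types shared across the pipeline stages."""


class PdskitError(Exception):
    """Base class for all pdskit errors."""


class NameNormalizationError(PdskitError):
    """Raised for empty or whitespace-only metabolite names."""


class DatabaseFormatError(PdskitError):
    """Raised when a database snapshot violates its schema."""


class InputError(PdskitError):
    """Raised for invalid user-supplied arguments."""


class ProfileFormatError(PdskitError):
    """Raised when an intensity table violates the profile contract."""


class PathwaySkipped(PdskitError):
    """Raised internally when a pathway cannot be scored; carries the reason."""

    def __init__(self, pathway_id: str, reason: str):
        super().__init__(f"pathway {pathway_id} skipped: {reason}")
        self.pathway_id = pathway_id
        self.reason = reason


class DegenerateCloudError(PdskitError):
    """Raised when a point cloud has no spread (all points identical)."""


class EmptyResultError(PdskitError):
    """Raised when no pathway survives eligibility filtering."""


class SplitError(PdskitError):
    """Raised when a train/test partition would lose a phenotype class."""


class MetricError(PdskitError):
    """Raised when a performance metric is undefined (e.g. single-class test set)."""


class ConfigError(PdskitError):
    """Raised for invalid pipeline configuration before any computation."""
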