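"""Exception hierarchy shared across the package."""


class BehavArchError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BehavArchError, ValueError):
    """Invalid simulator or pipeline configuration."""


class SchemaError(BehavArchError, ValueError):
    """A table does not conform to the expected column schema."""


class EmptyInputError(BehavArchError, ValueError):
    """An operation received an empty collection where records are required."""


class EmptyPanelError(BehavArchError, ValueError):
    """All SNPs or all lines were removed from a genotype panel."""


class InsufficientDataError(BehavArchError, ValueError):
    """Too few observations to run the requested test."""


class DegenerateInputError(BehavArchError, ValueError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class ScreenedOutError(BehavArchError, ValueError):
    """A trait or trait pair fails the pre-test screening rule."""


class UnknownIdError(BehavArchError, KeyError):
    """A requested SNP, trait, or category identifier is not present."""


class FormatError(BehavArchError, ValueError):
    """A file on disk is not in the expected format."""
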