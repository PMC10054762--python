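"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`MicrostabError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class MicrostabError(Exception):
    """Base class for all package errors."""


class SchemaError(MicrostabError):
    """A delimited-text table is missing a required column."""


class MeasurementValidationError(MicrostabError):
    """A table row violates a measurement invariant (e.g. negative area)."""


class MissingInternalStandardError(MicrostabError):
    """Internal-standard area is absent or zero where a ratio is required."""


class InsufficientDataError(MicrostabError):
    """Fewer points/replicates/curves than the operation requires."""


class DegenerateFitError(MicrostabError):
    """Singular design or zero slope: the fit cannot be used."""


class NoDepletionError(MicrostabError):
    """Depletion slope is non-negative; half-life is undefined (stable substrate)."""


class NoLinearPhaseError(MicrostabError):
    """Automatic window selection found no prefix meeting the r-squared floor."""


class NormalizationError(MicrostabError):
    """Time course lacks a usable t=0 baseline."""


class IncompleteRunError(MicrostabError):
    """Acceptance evaluation is missing statistics for a configured level."""


class ConfigError(MicrostabError):
    """Malformed run configuration (bands, thresholds, file references)."""
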