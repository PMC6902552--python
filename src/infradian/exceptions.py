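"""Exception hierarchy for the infradian pipeline."""


class InfradianError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(InfradianError, ValueError):
    """Invalid or inconsistent configuration."""


class ParseError(InfradianError, ValueError):
    """A tabular input file could not be parsed."""


class MissingDataError(InfradianError, ValueError):
    """A trace does not cover a required time interval."""


class InsufficientDataError(InfradianError, ValueError):
    """Too little data for the requested computation."""


class NormalizationError(InfradianError, ValueError):
    """Internal-standard normalization is impossible for some mouse."""


class EmptyCohortError(InfradianError, ValueError):
    """Every mouse was excluded by quality control."""


class UndefinedCorrelationError(InfradianError, ValueError):
    """Pearson correlation is undefined (constant input)."""
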