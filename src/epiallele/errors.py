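"""Exception types shared across the package."""


class EpialleleError(Exception):
    """Base class for package errors."""


class ConfigurationError(EpialleleError):
    """A simulation or pipeline configuration value is invalid."""


class UndefinedRatioError(EpialleleError):
    """A ratio (ML, S, allele fraction) is requested with a zero denominator."""


class CoverageError(EpialleleError):
    """A site does not meet the minimum-coverage floor for calling."""


class UnsortedInputError(EpialleleError):
    """Streaming input was required to be coordinate-sorted but is not."""


class DependencyError(EpialleleError):
    """A pipeline stage is missing a required upstream output."""
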