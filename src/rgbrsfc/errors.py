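"""Exception hierarchy shared by the pipeline stages."""


class RGBRSFCError(Exception):
    """Base class for all package errors."""


class FormatError(RGBRSFCError):
    """Malformed or inconsistent input data (frames, labels, tables)."""


class ConfigError(RGBRSFCError):
    """Invalid configuration: bad parameter values, rank-deficient optics, ..."""


class TooShortError(RGBRSFCError):
    """A time series is too short for the requested operation."""


class RegistrationError(RGBRSFCError):
    """Motion estimation produced an implausible shift."""


class GenerationError(RGBRSFCError):
    """Phantom generation drove the forward model out of its valid range."""


class AnalysisError(RGBRSFCError):
    """A functional-map analysis could not be computed (degenerate input,
    non-convergence, ...)."""
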