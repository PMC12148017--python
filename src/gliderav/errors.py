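"""Exception hierarchy for gliderav.

All package errors derive from :class:`GliderarError` so callers can catch the
whole family; the subclasses mirror the kinds of failure the pipeline reports
(bad file, bad argument, unusable signal, failed estimation, bad config).
"""


class GliderarError(Exception):
    """Base class for all gliderav errors."""


class FormatError(GliderarError):
    """A file does not conform to the expected tag/profile dialect."""


class DataError(GliderarError):
    """A file parses but its contents violate a data invariant."""


class AnalysisError(GliderarError):
    """A signal cannot support the requested analysis (too short, degenerate)."""


class EstimationError(GliderarError):
    """A parameter estimation has no usable input or no solution."""


class ConfigurationError(GliderarError):
    """The pipeline/environment configuration is incomplete or inconsistent."""
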