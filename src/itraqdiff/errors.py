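"""Exception hierarchy.

Every error raised by the package derives from :class:`ItraqDiffError` so
callers (and the CLI exit-code mapping) can distinguish configuration
mistakes, malformed data, and numerical fit failures.
"""


class ItraqDiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ItraqDiffError):
    """Invalid configuration value, unknown contrast, inconsistent options."""


class SchemaError(ItraqDiffError):
    """Input table is missing required columns."""


class ValidationError(ItraqDiffError):
    """Input rows violate the declared field invariants."""


class FitError(ItraqDiffError):
    """The Gaussian null could not be fitted (degenerate histogram)."""


class UndefinedTestError(ItraqDiffError):
    """A rank test has no defined statistic (e.g. all paired differences zero)."""
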