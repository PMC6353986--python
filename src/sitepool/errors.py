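"""Exception hierarchy for sitepool.

Every error raised by the library derives from :class:`SitepoolError`, so
callers can catch one base class at pipeline boundaries (e.g. the CLI).
"""


class SitepoolError(Exception):
    """Base class for all sitepool errors."""


class ConfigurationError(SitepoolError):
    """Invalid configuration value; the message names the offending field."""


class LookupDomainError(SitepoolError, KeyError):
    """A requested domain is not present in the configuration or table."""


class InsufficientDataError(SitepoolError):
    """Too few complete cases to fit the requested model."""


class CollinearityError(SitepoolError):
    """The fixed-effects design matrix is singular."""


class DesignError(SitepoolError):
    """The site structure cannot support the analysis (e.g. a single site)."""


class DegenerateScaleError(SitepoolError):
    """The pooled SD is zero, so standardised differences are undefined."""


class EstimationError(SitepoolError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class ComparisonError(SitepoolError):
    """Model fits are not comparable (different samples or objectives)."""
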