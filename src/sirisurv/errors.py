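"""Exception hierarchy shared across the package."""


class SirisurvError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SirisurvError, ValueError):
    """A configuration object violates one of its invariants."""


class DomainError(SirisurvError, ValueError):
    """An input value lies outside the domain of an operation."""


class UndefinedResultError(SirisurvError, ValueError):
    """The requested statistic is undefined for the given data
    (e.g. no censoring-evaluable pair, no cases at a horizon)."""
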