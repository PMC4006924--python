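"""Exception types shared across the package."""


class SepsiskitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SepsiskitError):
    """An input file or in-memory structure violates a contract.

    Messages always name the offending identifier(s) so callers can
    locate the problem in their files.
    """


class DesignError(SepsiskitError):
    """A synthetic-data design or pipeline configuration is invalid."""


class DegenerateResultError(SepsiskitError):
    """A computation reached a defined-but-degenerate state (e.g. D = 0
    in a distance-from-reference score, which has no logarithm)."""
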