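"""Exception hierarchy for endosex.

All package-specific failures derive from :class:`EndosexError` so callers
can catch one base class at pipeline boundaries.
"""


class EndosexError(Exception):
    """Base class for all endosex errors."""


class SchemaError(EndosexError):
    """A required column is missing or a table has the wrong shape."""


class ValidationError(EndosexError):
    """One or more rows violate a dataset invariant.

    Carries ``diagnostics``: a list of ``(row_label, rule, message)`` tuples,
    one per rejected row.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class UndefinedProbabilityError(EndosexError):
    """A conditional probability has an empty conditioning event (0/0)."""


class BandCollapseError(EndosexError):
    """The female likelihood threshold exceeds the male one.

    Happens when the sexes are so well separated that the "unknown" band
    inverts; callers should fall back to the equal-error threshold.
    """


class NoThresholdError(EndosexError):
    """The smoothed probability curve never reaches the requested level."""


class SplineFitError(EndosexError):
    """Too few defined probability points to fit a smoothing spline."""


class BootstrapError(EndosexError):
    """Too many bootstrap replicates failed to produce an estimate."""
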