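"""Exception hierarchy for the mismatch-demography pipeline.

Errors are split into three broad families: configuration problems (bad
column mappings, missing tables), data validation problems (rows violating
invariants, reported with their row index), and estimation problems
(quantities that are undefined for the data at hand, e.g. a flowering
phenology with no recorded flowers).
"""


class MatchdemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MatchdemError):
    """A config file, column mapping or CLI invocation is invalid."""


class ValidationError(MatchdemError):
    """Input rows violate the table invariants.

    ``rows`` carries the 0-based data-row indices (header excluded) of the
    offending records.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class ContractError(MatchdemError):
    """Arguments violate an operation's preconditions (caller bug)."""


class UndefinedPhenologyError(MatchdemError):
    """No positive abundance: a weighted mean date cannot be formed."""


class CannotFitError(MatchdemError):
    """A regression cannot be fitted (too few points, degenerate design)."""


class UndefinedDemographyError(MatchdemError):
    """No usable year-to-year transition: growth rate undefined."""


class InsufficientDataError(MatchdemError):
    """Fewer observations than the analysis requires."""
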