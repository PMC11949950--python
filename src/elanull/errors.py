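"""Exception hierarchy for elanull.

Every error raised on bad user input derives from :class:`ValidityError`
(a ``ValueError``), so callers can catch one type for input problems while
letting genuine numerical failures (:class:`ConvergenceError`) propagate.
"""


class ElanullError(Exception):
    """Base class for all elanull errors."""


class ValidityError(ElanullError, ValueError):
    """Invalid input: broken invariants, mismatched shapes, bad parameters."""


class StationarityError(ValidityError):
    """A VAR model whose lag-1 matrix has spectral radius >= 1."""


class CapacityError(ValidityError):
    """Problem size exceeds what exact 2^N enumeration supports."""


class ConvergenceError(ElanullError, RuntimeError):
    """An iterative fit failed to reach its tolerance."""


class FeasibilityError(ValidityError):
    """Requested binary moments lie outside the Frechet-feasible region."""


class DegenerateStatisticError(ElanullError, ValueError):
    """A correlation or test statistic is undefined (zero variance)."""


class OffdiagIneligibleError(ElanullError):
    """Off-diagonal transition-matrix comparison requested with too few
    basins.  Recorded by pipelines as an ineligible comparison, not fatal."""


class ParseError(ElanullError, ValueError):
    """Malformed delimited-text input; the message names the offending line."""
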