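"""Exception hierarchy.

Every failure mode the pipeline can raise deliberately has a named class so
callers (and the CLI) can distinguish validation problems, degenerate inputs
and numerical failures without string matching.
"""


class PolyprecError(Exception):
    """Base class for all package errors."""


class ValidationError(PolyprecError):
    """A dataset violates the documented schema or referential integrity."""


class MissingColumnError(ValidationError):
    """An input table lacks one of its required header columns."""


class UnknownIdError(ValidationError):
    """An event or offspring row references an id absent from the roster."""


class DuplicateEventError(ValidationError):
    """Two mating events share the same (vial, day, seq) slot."""


class DayRangeError(ValidationError):
    """A day or lay_day value falls outside the 1..4 experimental window."""


class RosterError(ValidationError):
    """Roster-level invariant violated (focal count, marker/role mismatch...)."""


class NoDataError(PolyprecError):
    """A computation was asked for data that is not there (vial, empty set)."""


class DegenerateInputError(PolyprecError):
    """Input is formally valid but statistically degenerate (zero variance...)."""


class SingularDesignError(PolyprecError):
    """A regression design matrix is rank deficient."""


class CapacityError(PolyprecError):
    """Requested computation exceeds a hard combinatorial guard."""


class FittingError(PolyprecError):
    """A model fit failed or produced an internally inconsistent result."""
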