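"""Exception hierarchy.

``ValidationError`` covers malformed inputs and contract violations
(CLI exit code 2); ``DataQualityError`` covers inputs that are structurally
fine but biologically unusable, e.g. unmappable sequences or cohorts with
nothing callable (CLI exit code 3).
"""


class HaplomigError(Exception):
    """Base class for package errors."""


class ValidationError(HaplomigError, ValueError):
    """Malformed input or violated precondition."""


class DataQualityError(HaplomigError):
    """Structurally valid input that cannot be analyzed."""


class UnmappableSequenceError(DataQualityError):
    """No alignment shift places the read on the reference acceptably."""


class UndefinedStatisticError(DataQualityError):
    """A statistic is undefined for the given counts (e.g. M with 0/0)."""
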