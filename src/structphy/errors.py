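"""Exception hierarchy shared by all structphy modules."""


class StructphyError(Exception):
    """Base class for all structphy errors."""


class ValidationError(StructphyError):
    """Input data violates a structural invariant (length, bracket balance, alphabet)."""


class FormatError(StructphyError):
    """A file or serialized text could not be parsed."""


class UsageError(StructphyError):
    """An operation was called with arguments outside its contract."""


class UndefinedDistanceError(StructphyError):
    """No comparable sites/columns between two rows or profiles."""


class SaturationError(StructphyError):
    """Observed mismatch fraction beyond the correction's domain."""


class UndefinedStatisticError(StructphyError):
    """A summary statistic has an empty domain (e.g. no supported edges)."""
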