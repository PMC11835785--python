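"""Exception hierarchy.

All package errors derive from :class:`AfRelapseError` so callers can catch
one base class.  Input/schema problems and infeasible statistical operations
are kept distinct because the CLI maps them to different exit codes.
"""


class AfRelapseError(Exception):
    """Base class for all errors raised by afrelapse."""


class SchemaMismatchError(AfRelapseError):
    """Data refer to variables or states that the schema does not define."""


class InvalidParameterError(AfRelapseError):
    """A numeric or structural parameter is outside its admissible range."""


class InvalidConstraintsError(AfRelapseError):
    """Whitelist/blacklist arc constraints are contradictory or cyclic."""


class ImpossibleEvidenceError(AfRelapseError):
    """Conditioning event has probability zero under the fitted network.

    Raised instead of returning NaN: silently propagating NaN scores would
    corrupt downstream AUC computations.
    """


class InfeasibleStatisticError(AfRelapseError):
    """A statistic is undefined for the given data (e.g. one-class AUC)."""
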