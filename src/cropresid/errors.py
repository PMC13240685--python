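"""Exception hierarchy for cropresid.

All package-specific failures derive from :class:`CropResidError` so callers
can catch one base class at pipeline boundaries.
"""


class CropResidError(Exception):
    """Base class for all cropresid errors."""


class SchemaError(CropResidError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(CropResidError):
    """A value violates a domain invariant (negative half-life, fractions not
    summing to one, duplicate replicate keys, ...)."""


class InsufficientDataError(CropResidError):
    """Too few distinct observations to fit the requested model."""


class NonDissipatingError(CropResidError):
    """A residue series does not decay: the fitted rate constant is <= 0.

    Raised instead of silently clamping, so non-physical fits are never
    propagated into half-life or risk calculations.
    """


class FitConvergenceError(CropResidError):
    """The nonlinear least-squares optimiser failed to converge."""


class UndefinedStatisticError(CropResidError):
    """A validation statistic is undefined for this input (e.g. zero total
    sum of squares, or all-zero predictions for a relative error)."""


class AlignmentError(CropResidError):
    """Paired or superposed series do not share a common time grid."""


class ConfigurationError(CropResidError):
    """A simulation or risk configuration is incomplete or inconsistent."""


class StabilityError(CropResidError):
    """The integration step is too coarse for the fastest rate in the system
    (raised only in strict mode; otherwise a warning is emitted)."""
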