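"""Exception hierarchy.

All package errors derive from :class:`CDQuantError`; parameter-level
problems additionally derive from :class:`ValueError` so that callers who
do not care about the fine-grained taxonomy can catch the builtin.
"""


class CDQuantError(Exception):
    """Base class for all cdquant errors."""


class InvalidParameterError(CDQuantError, ValueError):
    """A scalar argument violates its documented domain (e.g. l <= 0)."""


class DegenerateAnalyteError(InvalidParameterError):
    """The analyte is achiral (delta_eps == 0): no CD-based quantification."""


class InvalidDesignError(InvalidParameterError):
    """A mixture design is inconsistent (volume fractions do not sum to 1)."""


class InvalidReferenceError(InvalidParameterError):
    """A reference (calculated) concentration is non-positive."""


class InsufficientDataError(CDQuantError, ValueError):
    """Too few calibration points to fit a line."""


class DegenerateDesignError(CDQuantError, ValueError):
    """All calibration points share one concentration: slope unidentifiable."""


class FlatResponseError(CDQuantError, ValueError):
    """Fitted (or supplied) slope is indistinguishable from zero."""


class WindowRangeError(CDQuantError, ValueError):
    """A requested wavelength/time window falls outside the measured grid."""


class FormatError(CDQuantError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class DataValidationError(CDQuantError, ValueError):
    """Parsed data violate an invariant (non-monotone grid, negative time...)."""


class InfeasibleMeasurementError(CDQuantError):
    """CD difference exceeds the LC sum, implying a negative concentration."""

    def __init__(self, c_a: float, c_b: float, message: str | None = None):
        self.c_a = c_a
        self.c_b = c_b
        super().__init__(
            message
            or f"infeasible measurement: |c1 - c2| = {c_a:g} mM exceeds "
            f"c1 + c2 = {c_b:g} mM"
        )
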