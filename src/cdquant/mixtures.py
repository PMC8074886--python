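"""L/D deconvolution: combine a CD difference with an LC sum.

The two enantiomers of a chiral analyte have exactly opposite CD responses
and identical achiral-LC responses. A mixture measurement therefore yields
two scalars:

    c_a = |c1 - c2|   (from the CD calibration curve; the sign of the
                       Cotton signal says which enantiomer is in excess)
    c_b =  c1 + c2    (from the achiral-LC calibration curve, where the
                       enantiomers co-elute)

and the individual concentrations follow from the linear system

    c1 = (c_b + s * c_a) / 2,   c2 = (c_b - s * c_a) / 2,

with s = +1 for L excess, -1 for D excess, and a racemic split when the CD
signal is below detection. The enantiomeric excess is
ee = 100 * (c1 - c2) / (c1 + c2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .calibration import (
    CalibrationCurve,
    SignalExtractionRule,
    extract_signal,
    integrate_peak,
    invert_calibration,
)
from .errors import (
    InfeasibleMeasurementError,
    InvalidDesignError,
    InvalidParameterError,
    InvalidReferenceError,
)
from .simulate import CDSpectrum, Chromatogram


@dataclass(frozen=True)
class MixtureDesign:
    """A gravimetric mixture: equal-concentration L and D stocks combined
    at volume fractions ``ratio_l : ratio_d`` (must sum to 1)."""

    c_stock: float  # mM, concentration of each stock before mixing
    ratio_l: float
    ratio_d: float

    def __post_init__(self) -> None:
        if self.c_stock < 0 or self.ratio_l < 0 or self.ratio_d < 0:
            raise InvalidDesignError("design fields must be non-negative")
        if not math.isclose(self.ratio_l + self.ratio_d, 1.0, abs_tol=1e-9):
            raise InvalidDesignError(
                f"volume fractions must sum to 1, got "
                f"{self.ratio_l!r} + {self.ratio_d!r}"
            )


def expected_mixture(design: MixtureDesign) -> tuple[float, float]:
    """Nominal (c1, c2) in mM implied by a mixture design."""
    return design.c_stock * design.ratio_l, design.c_stock * design.ratio_d


@dataclass(frozen=True)
class MixtureMeasurement:
    """The two observables of one mixture: CD difference and LC sum.

    ``excess_sign`` is +1 when the net Cotton effect is positive (L excess),
    -1 when negative (D excess) and 0 when the CD signal is below the
    racemic tolerance.
    """

    c_a: float          # |c1 - c2|, mM
    excess_sign: int    # +1 | -1 | 0
    c_b: float          # c1 + c2, mM

    def __post_init__(self) -> None:
        if self.c_a < 0 or self.c_b < 0:
            raise InvalidParameterError("c_a and c_b must be >= 0 mM")
        if self.excess_sign not in (-1, 0, 1):
            raise InvalidParameterError(
                f"excess_sign must be -1, 0 or +1, got {self.excess_sign!r}"
            )


@dataclass
class MixtureResult:
    """Deconvolved enantiomer concentrations and diagnostics."""

    c1: float  # L, mM
    c2: float  # D, mM
    ee: float  # enantiomeric excess, %
    measurement: MixtureMeasurement
    flags: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)
    uncertainty: dict | None = None


def solve_enantiomers(
    m: MixtureMeasurement,
    *,
    racemic_tol: float = 1e-9,
    clip_infeasible: bool = False,
) -> MixtureResult:
    """Solve the two-by-two linear system for (c1, c2).

    Raises :class:`InfeasibleMeasurementError` when ``c_a > c_b`` (one
    concentration would be negative), unless ``clip_infeasible`` is set, in
    which case the minor component is clipped to zero and the result
    flagged. With ``excess_sign == 0`` the measurement must be racemic to
    within ``racemic_tol``.
    """
    flags: list[str] = []
    c_a, c_b, s = m.c_a, m.c_b, m.excess_sign
    if s == 0:
        if c_a > racemic_tol:
            raise InvalidParameterError(
                f"excess_sign 0 requires c_a <= {racemic_tol:g} mM, got {c_a:g}"
            )
        c_a = 0.0
    if c_a > c_b:
        if not clip_infeasible:
            raise InfeasibleMeasurementError(c_a, c_b)
        c_a = c_b
        flags.append("clipped_infeasible")
    c1 = (c_b + s * c_a) / 2.0
    c2 = (c_b - s * c_a) / 2.0
    ee = 0.0 if c_b == 0 else 100.0 * (c1 - c2) / c_b
    return MixtureResult(c1=c1, c2=c2, ee=ee, measurement=m, flags=flags)


def diff_percent(exp: float, cal: float) -> float:
    """Relative error statistic, percent: ``100 * |exp - cal| / cal``.

    ``cal`` is the reference (calculated) concentration and must be
    positive. Rounding to one decimal happens only at the reporting layer.
    """
    if cal <= 0:
        raise InvalidReferenceError(f"reference concentration must be > 0, got {cal!r}")
    return 100.0 * abs(exp - cal) / cal


def quantify_mixture(
    cd_spec: CDSpectrum,
    chrom: Chromatogram,
    cd_curve: CalibrationCurve,
    lc_curve: CalibrationCurve,
    *,
    lc_window: tuple[float, float],
    cd_rule: SignalExtractionRule | None = None,
    baseline_windows: Sequence[tuple[float, float]] | None = None,
    clip_infeasible: bool = False,
    racemic_tol: float | None = None,
    uncertainty: bool = False,
) -> MixtureResult:
    """Full mixture pipeline: spectrum + chromatogram -> (c1, c2, ee).

    The CD signal is extracted (``cd_rule`` defaults to the rule stored on
    the CD curve) and inverted with sign preserved: the signed value ``d``
    gives ``c_a = |d|`` and the excess sign. Signed values below
    ``max(LOD, 1e-9)`` — or below ``racemic_tol`` if given — are treated as
    racemic, since a below-detection sign is noise. The LC peak is
    integrated over ``lc_window`` (min) and inverted to ``c_b``. All
    intermediates are retained in ``result.details``.

    With ``uncertainty=True`` and residual standard errors available on both
    curves, first-order standard deviations for c1 and c2 are attached.
    """
    rule = cd_rule or cd_curve.extraction or SignalExtractionRule()
    wavelength, theta = extract_signal(cd_spec, rule)
    d, cd_in_range = invert_calibration(cd_curve, theta)
    tol = max(cd_curve.lod, 1e-9) if racemic_tol is None else racemic_tol
    if abs(d) < tol:
        c_a, sign = 0.0, 0
    else:
        c_a, sign = abs(d), (1 if d > 0 else -1)

    area = integrate_peak(chrom, *lc_window, baseline_windows=baseline_windows)
    c_b, lc_in_range = invert_calibration(lc_curve, area)
    flags: list[str] = []
    if c_b < 0:
        flags.append("negative_total_clamped")
        c_b = 0.0
    if not cd_in_range:
        flags.append("cd_out_of_range")
    if not lc_in_range:
        flags.append("lc_out_of_range")

    m = MixtureMeasurement(c_a=c_a, excess_sign=sign, c_b=c_b)
    result = solve_enantiomers(m, racemic_tol=tol, clip_infeasible=clip_infeasible)
    result.flags = flags + result.flags
    result.details = {
        "cd_peak_wavelength_nm": wavelength,
        "cd_theta_mdeg": theta,
        "cd_signed_conc_mM": d,
        "lc_area_mau_min": area,
        "racemic_tol_mM": tol,
    }
    if uncertainty and cd_curve.residual_sd is not None and lc_curve.residual_sd is not None:
        sd_ca = cd_curve.residual_sd / abs(cd_curve.slope)
        sd_cb = lc_curve.residual_sd / abs(lc_curve.slope)
        sd_c = 0.5 * math.hypot(sd_ca, sd_cb)
        result.uncertainty = {"c1_sd_mM": sd_c, "c2_sd_mM": sd_c,
                              "c_a_sd_mM": sd_ca, "c_b_sd_mM": sd_cb}
    return result
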