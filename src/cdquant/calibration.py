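"""Calibration curves: signal extraction, OLS fitting, LOD/LOQ, inversion.

A calibration curve is an ordinary least-squares line

    signal = slope * conc + intercept

fitted to a standard-dilution series, used in the inverse direction
(``conc = (signal - intercept) / slope``) to predict unknown concentrations.
Detection limits follow the signal-to-noise convention: LOD at S/N = 3 and
LOQ at S/N = 10, converted to concentration units through the slope
(``3 * sigma / |slope|`` and ``10 * sigma / |slope|``).

The CD signal of a spectrum is a single scalar extracted either at the
point of maximum absolute ellipticity inside a window (default 190-220 nm,
the amino-acid Cotton region) or at a fixed wavelength; the sign is always
retained, since it encodes which enantiomer is in excess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    FlatResponseError,
    InsufficientDataError,
    InvalidParameterError,
    WindowRangeError,
)
from .simulate import CDSpectrum, Chromatogram, COTTON_WINDOW

#: Fitted slopes with absolute value below this are treated as flat response.
SLOPE_EPS = 1e-12


@dataclass(frozen=True)
class SignalExtractionRule:
    """How to reduce a CD spectrum to one scalar signal.

    mode 'peak': signed ellipticity at the grid point of maximum |theta|
    within [window_lo, window_hi]; exact ties resolve to the lowest
    wavelength. mode 'fixed': theta at the grid point nearest ``wavelength``.
    """

    mode: str = "peak"
    window_lo: float = COTTON_WINDOW[0]
    window_hi: float = COTTON_WINDOW[1]
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("peak", "fixed"):
            raise InvalidParameterError(
                f"mode must be 'peak' or 'fixed', got {self.mode!r}"
            )
        if self.mode == "peak" and not self.window_lo < self.window_hi:
            raise InvalidParameterError(
                f"window_lo < window_hi required, got "
                f"({self.window_lo!r}, {self.window_hi!r})"
            )
        if self.mode == "fixed" and self.wavelength is None:
            raise InvalidParameterError("fixed mode requires a wavelength")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted calibration line with diagnostics and working range.

    slope/intercept are in signal units (mdeg for CD, mAU·min for LC) per mM
    and signal units respectively. ``conc_lo``/``conc_hi`` bracket the
    concentrations of the standards; lod/loq are in mM. ``residual_sd`` is
    the residual standard error of the fit (used for optional uncertainty
    propagation).
    """

    slope: float
    intercept: float
    r_squared: float
    conc_lo: float
    conc_hi: float
    lod: float
    loq: float
    modality: str = "CD"
    extraction: SignalExtractionRule | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if abs(self.slope) < SLOPE_EPS:
            raise FlatResponseError(f"slope {self.slope!r} is indistinguishable from 0")
        if not self.conc_lo < self.conc_hi:
            raise InvalidParameterError(
                f"conc_lo < conc_hi required, got ({self.conc_lo!r}, {self.conc_hi!r})"
            )
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidParameterError(f"r_squared must lie in [0,1], got {self.r_squared!r}")
        if self.lod > self.loq:
            raise InvalidParameterError("lod must not exceed loq")

    def predict(self, conc_mM: float) -> float:
        """Forward prediction: expected signal at a concentration."""
        return self.slope * conc_mM + self.intercept


def extract_signal(
    spectrum: CDSpectrum, rule: SignalExtractionRule | None = None
) -> tuple[float, float]:
    """Reduce a spectrum to ``(wavelength_nm, theta_mdeg)`` per the rule.

    The sign of theta is retained: an excess of the L-enantiomer gives a
    positive Cotton signal in 190-220 nm, an excess of D a negative one.
    """
    rule = rule or SignalExtractionRule()
    lam, th = spectrum.wavelengths, spectrum.theta
    if lam.size == 0:
        raise WindowRangeError("spectrum is empty")
    if rule.mode == "peak":
        if rule.window_lo < lam[0] or rule.window_hi > lam[-1]:
            raise WindowRangeError(
                f"window [{rule.window_lo:g}, {rule.window_hi:g}] nm falls "
                f"outside the measured grid [{lam[0]:g}, {lam[-1]:g}] nm"
            )
        mask = (lam >= rule.window_lo) & (lam <= rule.window_hi)
        if not mask.any():
            raise WindowRangeError("no grid points inside the extraction window")
        sub_lam, sub_th = lam[mask], th[mask]
        i = int(np.argmax(np.abs(sub_th)))  # first max: lowest-wavelength tie-break
        return float(sub_lam[i]), float(sub_th[i])
    if not lam[0] <= rule.wavelength <= lam[-1]:
        raise WindowRangeError(
            f"wavelength {rule.wavelength:g} nm outside measured grid "
            f"[{lam[0]:g}, {lam[-1]:g}] nm"
        )
    i = int(np.argmin(np.abs(lam - rule.wavelength)))
    return float(lam[i]), float(th[i])


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Detection/quantification limits in mM from noise and slope.

    LOD = 3 * sigma / |slope| (S/N = 3), LOQ = 10 * sigma / |slope|
    (S/N = 10).
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd!r}")
    if abs(slope) < SLOPE_EPS:
        raise FlatResponseError("zero slope: detection limit undefined")
    return 3.0 * noise_sd / abs(slope), 10.0 * noise_sd / abs(slope)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    modality: str = "CD",
    *,
    extraction: SignalExtractionRule | None = None,
    noise_sd: float | None = None,
) -> CalibrationCurve:
    """Fit an OLS calibration line to ``(conc_mM, signal)`` pairs.

    ``r_squared = 1 - SSE/SST``; the working range is set by the extreme
    standard concentrations. If ``noise_sd`` is not given, the residual
    standard error ``sqrt(SSE / (n - 2))`` stands in for the instrument
    noise when converting to LOD/LOQ.
    """
    pts = [(float(c), float(s)) for c, s in points]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need at least 3 calibration points, got {len(pts)}"
        )
    conc = np.array([c for c, _ in pts])
    sig = np.array([s for _, s in pts])
    if np.unique(conc).size < 2:
        raise DegenerateDesignError(
            "all calibration points share one concentration; slope is "
            "unidentifiable"
        )
    res = stats.linregress(conc, sig)
    slope, intercept = float(res.slope), float(res.intercept)
    if abs(slope) < SLOPE_EPS:
        raise FlatResponseError(
            f"fitted slope {slope:.3e} is indistinguishable from 0"
        )
    fitted = slope * conc + intercept
    sse = float(np.sum((sig - fitted) ** 2))
    sst = float(np.sum((sig - sig.mean()) ** 2))
    r_squared = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - sse / sst))
    resid_sd = float(np.sqrt(sse / (len(pts) - 2)))
    sigma = resid_sd if noise_sd is None else float(noise_sd)
    lod, loq = lod_loq(sigma, slope)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        conc_lo=float(conc.min()),
        conc_hi=float(conc.max()),
        lod=lod,
        loq=loq,
        modality=modality,
        extraction=extraction if extraction is not None else (
            SignalExtractionRule() if modality == "CD" else None
        ),
        residual_sd=resid_sd,
    )


def invert_calibration(curve: CalibrationCurve, signal: float) -> tuple[float, bool]:
    """Inverse prediction: ``(signal - intercept) / slope``, sign preserved.

    A negative result on a CD curve fitted to L standards signals a
    D-enantiomer excess. ``in_range`` is False when |conc| falls outside the
    curve's working range or below its LOQ; out-of-range is flagged, never
    fatal.
    """
    conc = (float(signal) - curve.intercept) / curve.slope
    in_range = curve.conc_lo <= abs(conc) <= curve.conc_hi and abs(conc) >= curve.loq
    return conc, in_range


def integrate_peak(
    chrom: Chromatogram,
    t_lo: float,
    t_hi: float,
    *,
    baseline_windows: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Trapezoidal peak area (mAU·min) over [t_lo, t_hi], baseline-corrected.

    The baseline is the mean absorbance over the given baseline windows
    (regions flanking the peak); with no windows the raw trace is integrated
    as-is.
    """
    t, y = chrom.times, chrom.absorbance
    if not t_lo < t_hi:
        raise InvalidParameterError(f"t_lo < t_hi required, got ({t_lo!r}, {t_hi!r})")
    if t.size < 2:
        raise WindowRangeError("chromatogram has fewer than 2 points")
    if t_lo < t[0] or t_hi > t[-1]:
        raise WindowRangeError(
            f"integration window [{t_lo:g}, {t_hi:g}] min falls outside the "
            f"measured grid [{t[0]:g}, {t[-1]:g}] min"
        )
    baseline = 0.0
    if baseline_windows:
        sel = np.zeros(t.size, dtype=bool)
        for lo, hi in baseline_windows:
            if not lo < hi:
                raise InvalidParameterError(
                    f"baseline window ({lo!r}, {hi!r}) is not ordered"
                )
            sel |= (t >= lo) & (t <= hi)
        if not sel.any():
            raise WindowRangeError("baseline windows contain no grid points")
        baseline = float(y[sel].mean())
    mask = (t >= t_lo) & (t <= t_hi)
    if mask.sum() < 2:
        raise WindowRangeError("integration window contains fewer than 2 points")
    return float(np.trapezoid(y[mask] - baseline, t[mask]))
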