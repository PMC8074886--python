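"""Forward simulator for CD spectra and achiral-LC chromatograms.

The simulator emulates the measurement setup the analysis layers assume:

* Each chiral analyte is described for its L-enantiomer by a set of Gaussian
  Cotton bands (signed molar-CD amplitudes). The D-enantiomer is the exact
  mirror image, ``delta_eps_D(lambda) = -delta_eps_L(lambda)``, so a mixture
  contributes in proportion to the concentration *difference* c_L - c_D and
  a racemic mixture gives a null spectrum.
* Ellipticity is linear in concentration per wavelength (theta[mdeg] =
  3298 * delta_eps * c[mM] * l) with additive, homoscedastic, independent
  Gaussian instrument noise.
* On an achiral LC column the two enantiomers co-elute exactly, so the
  chromatogram is a single Gaussian peak whose area is linear in the *total*
  concentration c_L + c_D and independent of the L:D ratio, again with
  additive Gaussian noise.

The combination gives the identification strategy its leverage: CD measures
|c_L - c_D| (plus a sign), LC measures c_L + c_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import core
from .errors import DataValidationError, InvalidParameterError

#: Default wavelength grid, nm: covers the 190-220 nm amino-acid Cotton
#: region with margin on both sides.
DEFAULT_WAVELENGTH_GRID = np.arange(185.0, 260.0 + 0.25, 0.5)

#: Default chromatogram time grid, min.
DEFAULT_TIME_GRID = np.arange(0.0, 8.0 + 0.0025, 0.005)

#: Default additive instrument noise, mdeg (CD) and mAU (LC). Chosen so a
#: five-point calibration series on the bundled analytes routinely fits with
#: R² >= 0.999, the regime a well-maintained benchtop CD instrument reaches.
DEFAULT_NOISE_SD_CD = 0.02
DEFAULT_NOISE_SD_LC = 0.2

#: Signed CD extraction window, nm, where L-amino acids show positive and
#: D-amino acids negative Cotton effects.
COTTON_WINDOW = (190.0, 220.0)


@dataclass(frozen=True)
class CottonBand:
    """One Gaussian Cotton band of the L-enantiomer.

    amplitude is the peak molar CD at the band centre, L·mol⁻¹·cm⁻¹, signed.
    """

    center: float  # nm
    width: float   # Gaussian standard deviation, nm
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvalidParameterError(f"band width must be > 0, got {self.width!r}")


@dataclass(frozen=True)
class AnalyteSpec:
    """Ground-truth description of one chiral analyte (L-enantiomer).

    ``bands`` parameterise the molar-CD profile; ``retention_time`` /
    ``retention_width`` (min) place the co-eluting LC peak; and
    ``response_factor`` is the LC peak area (mAU·min) per mM of total
    analyte. The net Cotton amplitude over 190-220 nm must be positive:
    that window defines the L sign convention.
    """

    name: str
    bands: tuple[CottonBand, ...]
    retention_time: float
    retention_width: float
    response_factor: float

    def __post_init__(self) -> None:
        if not self.bands:
            raise InvalidParameterError("an analyte needs at least one Cotton band")
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.retention_width > 0:
            raise InvalidParameterError(
                f"retention_width must be > 0, got {self.retention_width!r}"
            )
        if not self.response_factor > 0:
            raise InvalidParameterError(
                f"response_factor must be > 0, got {self.response_factor!r}"
            )
        lo, hi = COTTON_WINDOW
        grid = np.linspace(lo, hi, 301)
        if np.trapezoid(self.delta_eps(grid), grid) <= 0:
            raise InvalidParameterError(
                f"analyte {self.name!r}: net Cotton amplitude in "
                f"{lo:g}-{hi:g} nm must be positive for the L-enantiomer"
            )

    def delta_eps(self, wavelengths) -> np.ndarray:
        """Molar CD of the L-enantiomer on a wavelength grid."""
        lam = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(lam)
        for b in self.bands:
            out += b.amplitude * np.exp(-0.5 * ((lam - b.center) / b.width) ** 2)
        return out


@dataclass
class CDSpectrum:
    """A measured or simulated CD spectrum (ellipticity in mdeg)."""

    wavelengths: np.ndarray
    theta: np.ndarray
    path_len: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.wavelengths.shape != self.theta.shape or self.wavelengths.ndim != 1:
            raise DataValidationError(
                "wavelengths and theta must be 1-D arrays of equal length"
            )
        if self.wavelengths.size and not np.all(np.diff(self.wavelengths) > 0):
            raise DataValidationError("wavelength grid must be strictly increasing")
        if not self.path_len > 0:
            raise InvalidParameterError(f"path_len must be > 0, got {self.path_len!r}")


@dataclass
class Chromatogram:
    """A measured or simulated achiral-LC trace (absorbance in mAU)."""

    times: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape or self.times.ndim != 1:
            raise DataValidationError(
                "times and absorbance must be 1-D arrays of equal length"
            )
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise DataValidationError("time grid must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise DataValidationError("time grid must be non-negative")


def ph_factor(ph: float, *, floor_acid: float = 0.35, floor_base: float = 0.35) -> float:
    """Multiplicative CD-signal attenuation as a function of pH.

    Amino-acid CD intensity is stable on a plateau from pH 3 to pH 8 and
    drops off toward strongly acidic or basic conditions. The plateau is
    modelled as exactly 1.0; outside it the factor ramps linearly down to a
    configurable floor reached at pH 1 (acid side) and pH 12 (base side)
    and stays at the floor beyond. This is a scalar attenuation only — band
    positions and shapes are not shifted.
    """
    if not 0 <= ph <= 14:
        raise InvalidParameterError(f"pH must lie in [0, 14], got {ph!r}")
    for floor in (floor_acid, floor_base):
        if not 0 <= floor <= 1:
            raise InvalidParameterError(f"pH floor must lie in [0, 1], got {floor!r}")
    if 3.0 <= ph <= 8.0:
        return 1.0
    if ph < 3.0:
        if ph <= 1.0:
            return floor_acid
        return floor_acid + (1.0 - floor_acid) * (ph - 1.0) / 2.0
    if ph >= 12.0:
        return floor_base
    return 1.0 + (floor_base - 1.0) * (ph - 8.0) / 4.0


def simulate_cd(
    analyte: AnalyteSpec,
    c_l: float,
    c_d: float,
    *,
    path_len: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD_CD,
    seed=None,
    grid: np.ndarray | None = None,
    ph: float | None = None,
) -> CDSpectrum:
    """Simulate the CD spectrum of an L/D mixture at c_l, c_d (mM).

    The noise-free signal at each wavelength is
    ``3298 * delta_eps_L(lambda) * (c_l - c_d) * path_len`` in mdeg — the
    mirror rule for the D-enantiomer is built in — optionally scaled by
    :func:`ph_factor`. Independent ``N(0, noise_sd²)`` noise is added per
    grid point; the same ``seed`` and inputs reproduce the spectrum exactly.
    """
    if c_l < 0 or c_d < 0:
        raise InvalidParameterError(
            f"concentrations must be >= 0 mM, got c_l={c_l!r}, c_d={c_d!r}"
        )
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd!r}")
    lam = DEFAULT_WAVELENGTH_GRID.copy() if grid is None else np.asarray(grid, float)
    scale = 1.0 if ph is None else ph_factor(ph)
    theta = core.theta_mdeg(analyte.delta_eps(lam), c_l - c_d, path_len) * scale
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, lam.size)
    return CDSpectrum(
        wavelengths=lam,
        theta=theta,
        path_len=path_len,
        label=f"{analyte.name} c_L={c_l:g}mM c_D={c_d:g}mM",
    )


def simulate_lc(
    analyte: AnalyteSpec,
    c_total: float,
    *,
    noise_sd: float = DEFAULT_NOISE_SD_LC,
    seed=None,
    grid: np.ndarray | None = None,
) -> Chromatogram:
    """Simulate the achiral-LC trace of ``c_total`` mM of analyte.

    Enantiomers co-elute exactly, so only the total concentration enters:
    one Gaussian peak at ``retention_time`` with area
    ``response_factor * c_total`` mAU·min, plus per-point Gaussian noise.
    """
    if c_total < 0:
        raise InvalidParameterError(f"c_total must be >= 0 mM, got {c_total!r}")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd!r}")
    t = DEFAULT_TIME_GRID.copy() if grid is None else np.asarray(grid, float)
    w = analyte.retention_width
    amplitude = analyte.response_factor * c_total / (w * math.sqrt(2.0 * math.pi))
    y = amplitude * np.exp(-0.5 * ((t - analyte.retention_time) / w) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, t.size)
    return Chromatogram(times=t, absorbance=y,
                        label=f"{analyte.name} c_total={c_total:g}mM")


def _child_seeds(seed, n: int):
    """Deterministic per-item seeds derived from one master seed."""
    return np.random.SeedSequence(seed).spawn(n)


def make_calibration_series(
    analyte: AnalyteSpec,
    concs,
    handedness: str = "L",
    *,
    noise_sd: float = DEFAULT_NOISE_SD_CD,
    seed=None,
    path_len: float = 1.0,
    grid: np.ndarray | None = None,
) -> list[tuple[float, CDSpectrum]]:
    """Simulate a standard-dilution CD series: one spectrum per concentration.

    Per-spectrum seeds are derived deterministically from the master seed,
    so the same call reproduces the whole series element-wise.
    """
    concs = list(concs)
    if not concs:
        raise InvalidParameterError("concs must be non-empty")
    if any(c < 0 for c in concs):
        raise InvalidParameterError("all concentrations must be >= 0 mM")
    if handedness not in ("L", "D"):
        raise InvalidParameterError(f"handedness must be 'L' or 'D', got {handedness!r}")
    out = []
    for c, child in zip(concs, _child_seeds(seed, len(concs))):
        c_l, c_d = (c, 0.0) if handedness == "L" else (0.0, c)
        out.append(
            (c, simulate_cd(analyte, c_l, c_d, path_len=path_len,
                            noise_sd=noise_sd, seed=child, grid=grid))
        )
    return out


def make_lc_series(
    analyte: AnalyteSpec,
    concs,
    *,
    noise_sd: float = DEFAULT_NOISE_SD_LC,
    seed=None,
    grid: np.ndarray | None = None,
) -> list[tuple[float, Chromatogram]]:
    """Simulate an LC standard series (total concentration per trace)."""
    concs = list(concs)
    if not concs:
        raise InvalidParameterError("concs must be non-empty")
    return [
        (c, simulate_lc(analyte, c, noise_sd=noise_sd, seed=child, grid=grid))
        for c, child in zip(concs, _child_seeds(seed, len(concs)))
    ]


def default_analytes() -> dict[str, AnalyteSpec]:
    """Bundled analyte fixtures loosely modelled on Leu, Pro and Met.

    The main-band amplitudes are tuned so the peak-ellipticity calibration
    slope (mdeg per mM at 1 cm) of each analyte equals its published
    single-analyte calibration slope — a convenience anchor for realistic
    signal magnitudes, not a claim about true molar-CD values. Retention
    parameters are generic reversed-phase values.
    """
    f = core.THETA_DEG_PER_DELTA_A
    return {
        "leu": AnalyteSpec(
            name="Leu",
            bands=(
                CottonBand(center=200.0, width=9.0, amplitude=0.1927 / f),
                CottonBand(center=238.0, width=7.0, amplitude=-0.03 / f),
            ),
            retention_time=4.2,
            retention_width=0.12,
            response_factor=9.5,
        ),
        "pro": AnalyteSpec(
            name="Pro",
            bands=(CottonBand(center=202.0, width=8.0, amplitude=1.0363 / f),),
            retention_time=3.1,
            retention_width=0.10,
            response_factor=14.0,
        ),
        "met": AnalyteSpec(
            name="Met",
            bands=(
                CottonBand(center=205.0, width=9.0, amplitude=0.1899 / f),
                CottonBand(center=235.0, width=6.0, amplitude=-0.25 * 0.1899 / f),
            ),
            retention_time=5.0,
            retention_width=0.14,
            response_factor=11.0,
        ),
    }
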