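"""Circular-dichroism signal model and unit conversions.

Circular dichroism (CD) is the differential absorption of left- versus
right-circularly polarised light by a chiral sample,

    dA = A_L - A_R = delta_eps * c * l,

where ``delta_eps`` is the molar circular dichroism (L·mol⁻¹·cm⁻¹), ``c``
the molar concentration (mol·L⁻¹) and ``l`` the cuvette path length (cm).
Spectra are conventionally reported as ellipticity in degrees,

    theta = 3298 * dA,

with 3298 treated here as an exact defined constant. Since the factor
between degrees and millidegrees (10³) cancels the factor between mol·L⁻¹
and mmol·L⁻¹ (10⁻³),

    theta[mdeg] = 3298 * delta_eps * c[mM] * l,

which is the form used by the simulator and calibration layers: instruments
report millidegrees, and bench concentrations are millimolar.

Everything in this module is pure scalar/array arithmetic; the calibration
and mixture modules build on it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateAnalyteError, InvalidParameterError

#: Ellipticity (degrees) per unit differential absorbance; exact by convention.
THETA_DEG_PER_DELTA_A = 3298.0

MDEG_PER_DEG = 1000.0


@dataclass(frozen=True)
class CDSignalParams:
    """Parameters of the CD signal law for one analyte at one wavelength.

    Attributes
    ----------
    delta_eps : molar circular dichroism, L·mol⁻¹·cm⁻¹ (signed; opposite
        sign for the two enantiomers of a compound).
    conc : molar concentration, mol·L⁻¹ (non-negative).
    path_len : cuvette path length, cm (strictly positive).
    """

    delta_eps: float
    conc: float
    path_len: float

    def __post_init__(self) -> None:
        if not self.path_len > 0:
            raise InvalidParameterError(
                f"path_len must be > 0 cm, got {self.path_len!r}"
            )
        if self.conc < 0:
            raise InvalidParameterError(f"conc must be >= 0, got {self.conc!r}")


def delta_absorbance(p: CDSignalParams) -> float:
    """Differential absorbance dA = delta_eps * c * l (dimensionless).

    The sign of the result follows the sign of ``delta_eps``.
    """
    return p.delta_eps * p.conc * p.path_len


def ellipticity_from_deltaA(delta_a: float) -> float:
    """Convert differential absorbance to ellipticity in degrees."""
    return THETA_DEG_PER_DELTA_A * delta_a


def deltaA_from_ellipticity(theta_deg: float) -> float:
    """Exact inverse of :func:`ellipticity_from_deltaA`."""
    return theta_deg / THETA_DEG_PER_DELTA_A


def conc_from_theta(theta_deg: float, delta_eps: float, path_len: float) -> float:
    """Invert the signal law: c = theta / (3298 * delta_eps * l), mol·L⁻¹.

    Raises
    ------
    DegenerateAnalyteError
        If ``delta_eps`` is zero (achiral analyte: theta carries no
        concentration information).
    InvalidParameterError
        If ``path_len`` is not strictly positive.
    """
    if delta_eps == 0:
        raise DegenerateAnalyteError(
            "delta_eps is 0: achiral analyte, concentration is not "
            "recoverable from a CD signal"
        )
    if not path_len > 0:
        raise InvalidParameterError(f"path_len must be > 0 cm, got {path_len!r}")
    return theta_deg / (THETA_DEG_PER_DELTA_A * delta_eps * path_len)


def theta_mdeg(delta_eps, conc_mM, path_len):
    """Ellipticity in millidegrees for a millimolar concentration.

    Accepts scalars or numpy arrays in any argument (broadcasting applies);
    the 10³ mdeg/deg and 10⁻³ M/mM factors cancel, leaving the same 3298
    constant.
    """
    return THETA_DEG_PER_DELTA_A * delta_eps * conc_mM * path_len


def conc_mM_from_theta_mdeg(theta_mdeg_val: float, delta_eps: float,
                            path_len: float) -> float:
    """Inverse of :func:`theta_mdeg` for scalar inputs (mM result)."""
    if delta_eps == 0:
        raise DegenerateAnalyteError(
            "delta_eps is 0: achiral analyte, concentration is not "
            "recoverable from a CD signal"
        )
    if not path_len > 0:
        raise InvalidParameterError(f"path_len must be > 0 cm, got {path_len!r}")
    return theta_mdeg_val / (THETA_DEG_PER_DELTA_A * delta_eps * path_len)
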