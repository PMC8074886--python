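"""File formats and run configuration.

Spectra and chromatograms travel as small two-column CSV files (comma
separated, ``.`` decimal, UTF-8) with ``#``-prefixed comment lines carrying
metadata:

    # cdquant spectrum v1
    # label: Leu c_L=8mM c_D=0mM
    # path_len_cm: 1
    wavelength_nm,ellipticity_mdeg
    185.0,0.0123

Calibration curves and mixture results serialise to JSON documents.
Parsing errors always name the offending line; structural problems
(non-monotone grids, negative times) surface as validation errors.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationCurve, SignalExtractionRule
from .errors import DataValidationError, FormatError, InvalidParameterError
from .mixtures import MixtureResult, diff_percent
from .simulate import (
    CDSpectrum,
    Chromatogram,
    COTTON_WINDOW,
    DEFAULT_NOISE_SD_CD,
    DEFAULT_NOISE_SD_LC,
)

SPECTRUM_HEADER = "wavelength_nm,ellipticity_mdeg"
CHROMATOGRAM_HEADER = "time_min,absorbance_mau"
SERIES_HEADER = "conc_mM,signal"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --- two-column CSV ---------------------------------------------------------

def _read_two_column(path, expected_header: str):
    """Shared reader: returns (metadata dict, col1 list, col2 list)."""
    path = Path(path)
    meta: dict[str, str] = {}
    col1: list[float] = []
    col2: list[float] = []
    saw_header = False
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not saw_header:
                if line != expected_header:
                    raise FormatError(
                        f"{path}, line {lineno}: expected header "
                        f"{expected_header!r}, got {line!r}"
                    )
                saw_header = True
                continue
            fields = next(csv.reader([line]))
            if len(fields) != 2:
                raise FormatError(
                    f"{path}, line {lineno}: expected 2 comma-separated "
                    f"values, got {len(fields)}"
                )
            try:
                col1.append(float(fields[0]))
                col2.append(float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    if not saw_header:
        raise FormatError(f"{path}: no header line {expected_header!r} found")
    if not col1:
        raise FormatError(f"{path}: no data rows")
    return meta, col1, col2


def read_spectrum(path) -> CDSpectrum:
    """Read a CD spectrum CSV (header ``wavelength_nm,ellipticity_mdeg``)."""
    meta, lam, theta = _read_two_column(path, SPECTRUM_HEADER)
    try:
        path_len = float(meta.get("path_len_cm", "1"))
    except ValueError as exc:
        raise FormatError(f"{path}: bad path_len_cm metadata: {exc}") from exc
    try:
        return CDSpectrum(wavelengths=lam, theta=theta, path_len=path_len,
                          label=meta.get("label", ""))
    except (DataValidationError, InvalidParameterError) as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: CDSpectrum, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# cdquant spectrum v1\n")
        if spectrum.label:
            fh.write(f"# label: {spectrum.label}\n")
        fh.write(f"# path_len_cm: {spectrum.path_len:.12g}\n")
        fh.write(SPECTRUM_HEADER + "\n")
        for lam, th in zip(spectrum.wavelengths, spectrum.theta):
            fh.write(f"{lam:.12g},{th:.12g}\n")


def read_chromatogram(path) -> Chromatogram:
    """Read an LC trace CSV (header ``time_min,absorbance_mau``).

    At least two points are required (a single sample cannot be
    integrated).
    """
    meta, t, y = _read_two_column(path, CHROMATOGRAM_HEADER)
    if len(t) < 2:
        raise DataValidationError(
            f"{path}: a chromatogram needs at least 2 points to integrate, got {len(t)}"
        )
    try:
        return Chromatogram(times=t, absorbance=y, label=meta.get("label", ""))
    except (DataValidationError, InvalidParameterError) as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_chromatogram(chrom: Chromatogram, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# cdquant chromatogram v1\n")
        if chrom.label:
            fh.write(f"# label: {chrom.label}\n")
        fh.write(CHROMATOGRAM_HEADER + "\n")
        for t, a in zip(chrom.times, chrom.absorbance):
            fh.write(f"{t:.12g},{a:.12g}\n")


def read_series(path) -> list[tuple[float, float]]:
    """Read a calibration series CSV with header ``conc_mM,signal``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != SERIES_HEADER.split(","):
        raise FormatError(
            f"{path}: expected header {SERIES_HEADER!r}, got "
            f"{','.join(map(str, df.columns))!r}"
        )
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return list(zip(df["conc_mM"].astype(float), df["signal"].astype(float)))


def write_series(points, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(SERIES_HEADER + "\n")
        for c, s in points:
            fh.write(f"{c:.12g},{s:.12g}\n")


# --- JSON documents ---------------------------------------------------------

CURVE_FORMAT = "cdquant.curve.v1"
RESULT_FORMAT = "cdquant.result.v1"


def curve_to_dict(curve: CalibrationCurve, analyte: str | None = None) -> dict:
    doc = {
        "format": CURVE_FORMAT,
        "modality": curve.modality,
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "conc_lo": curve.conc_lo,
        "conc_hi": curve.conc_hi,
        "lod": curve.lod,
        "loq": curve.loq,
        "residual_sd": curve.residual_sd,
    }
    if analyte:
        doc["analyte"] = analyte
    if curve.extraction is not None:
        e = curve.extraction
        doc["extraction"] = {
            "mode": e.mode, "window_lo": e.window_lo,
            "window_hi": e.window_hi, "wavelength": e.wavelength,
        }
    return doc


def curve_from_dict(doc: dict) -> CalibrationCurve:
    if doc.get("format") != CURVE_FORMAT:
        raise FormatError(
            f"not a calibration-curve document (format field "
            f"{doc.get('format')!r}, expected {CURVE_FORMAT!r})"
        )
    extraction = None
    if "extraction" in doc and doc["extraction"] is not None:
        e = doc["extraction"]
        extraction = SignalExtractionRule(
            mode=e["mode"], window_lo=e["window_lo"],
            window_hi=e["window_hi"], wavelength=e.get("wavelength"),
        )
    return CalibrationCurve(
        slope=doc["slope"], intercept=doc["intercept"],
        r_squared=doc["r_squared"], conc_lo=doc["conc_lo"],
        conc_hi=doc["conc_hi"], lod=doc["lod"], loq=doc["loq"],
        modality=doc.get("modality", "CD"), extraction=extraction,
        residual_sd=doc.get("residual_sd"),
    )


def save_curve(curve: CalibrationCurve, path, analyte: str | None = None) -> None:
    Path(path).write_text(
        json.dumps(curve_to_dict(curve, analyte), indent=2) + "\n", encoding="utf-8"
    )


def load_curve(path) -> CalibrationCurve:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        return curve_from_dict(doc)
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc


def result_to_dict(result: MixtureResult, precision: int = 2) -> dict:
    """JSON document for a mixture result; concentrations additionally
    reported rounded at the configured precision."""
    m = result.measurement
    return {
        "format": RESULT_FORMAT,
        "c1_mM": result.c1,
        "c2_mM": result.c2,
        "ee_pct": result.ee,
        "c1_mM_rounded": round_half_up(result.c1, precision),
        "c2_mM_rounded": round_half_up(result.c2, precision),
        "c_a_mM": m.c_a,
        "c_b_mM": m.c_b,
        "excess_sign": m.excess_sign,
        "flags": list(result.flags),
        "details": dict(result.details),
        "uncertainty": result.uncertainty,
    }


def save_result(result: MixtureResult, path, precision: int = 2) -> None:
    Path(path).write_text(
        json.dumps(result_to_dict(result, precision), indent=2) + "\n",
        encoding="utf-8",
    )


REPORT_COLUMNS = ["cal_L_mM", "cal_D_mM", "exp_L_mM", "exp_D_mM",
                  "diff_L_pct", "diff_D_pct"]


def result_report_row(
    result: MixtureResult,
    reference: tuple[float, float] | None = None,
    precision: int = 2,
) -> dict:
    """One benchmark-style report row: nominal, measured, relative error.

    With no reference the nominal and error columns are left empty.
    """
    row: dict[str, object] = dict.fromkeys(REPORT_COLUMNS, "")
    row["exp_L_mM"] = round_half_up(result.c1, precision)
    row["exp_D_mM"] = round_half_up(result.c2, precision)
    if reference is not None:
        cal_l, cal_d = reference
        row["cal_L_mM"] = round_half_up(cal_l, precision)
        row["cal_D_mM"] = round_half_up(cal_d, precision)
        row["diff_L_pct"] = round_half_up(diff_percent(result.c1, cal_l), 1)
        row["diff_D_pct"] = round_half_up(diff_percent(result.c2, cal_d), 1)
    return row


def format_report(rows: list[dict]) -> str:
    buf = _io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=REPORT_COLUMNS)
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable knobs shared by the CLI subcommands.

    Windows are (low, high) pairs: nm for the CD extraction window, min for
    the LC integration window. ``precision`` is the number of decimals used
    at the reporting layer (internal values stay full precision).
    """

    seed: int = 0
    noise_sd_cd: float = DEFAULT_NOISE_SD_CD
    noise_sd_lc: float = DEFAULT_NOISE_SD_LC
    cd_window: tuple[float, float] = COTTON_WINDOW
    lc_window: tuple[float, float] = (3.6, 4.8)
    clip_infeasible: bool = False
    precision: int = 2

    def __post_init__(self) -> None:
        for name in ("cd_window", "lc_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidParameterError(f"{name} must be ordered, got ({lo!r}, {hi!r})")
            setattr(self, name, (float(lo), float(hi)))
        if self.precision < 0:
            raise InvalidParameterError(f"precision must be >= 0, got {self.precision!r}")
        if self.noise_sd_cd < 0 or self.noise_sd_lc < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(**raw)
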