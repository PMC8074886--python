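# Methods

## The measurement model

Circular dichroism (CD) is the differential absorption of left- versus
right-circularly polarised light,

    ΔA = A_L − A_R = Δε · c · l,

with Δε the molar circular dichroism (L·mol⁻¹·cm⁻¹), c the molar
concentration and l the path length (cm). Spectra are reported as
ellipticity, θ = 3298·ΔA degrees; `cdquant` treats 3298 as an exact
defined constant (not 3298.2). Inverting gives the quantification law

    c = θ / (3298 · Δε · l).

The individual absorbances A_L and A_R never appear in the analysis; only
their difference ΔA is represented.

**Units.** Instruments report millidegrees, and bench concentrations are
millimolar. Because the mdeg/deg factor (10³) cancels the mM/M factor
(10⁻³), the working form is `θ[mdeg] = 3298 · Δε · c[mM] · l` with the
same constant. Degree/molar forms live in `cdquant.core`; everything above
that layer speaks mdeg and mM. Reported concentrations are rounded to two
decimals (errors to one decimal, half-up) only at the reporting layer;
internal values keep full precision.

## Mixture deconvolution

The two enantiomers of a chiral analyte have exactly mirrored CD responses
(Δε_D = −Δε_L) and identical achiral-LC responses (they co-elute on an
achiral column). Two calibrated channels therefore measure complementary
linear combinations:

* CD gives the signed difference: inverting the CD calibration curve on
  the mixture signal yields d with c_a = |d| = |c₁ − c₂| and the sign of d
  telling which enantiomer is in excess (L-amino acids give positive
  Cotton effects at 190–220 nm, D negative).
* LC gives the sum c_b = c₁ + c₂.

Solving the 2×2 system, with s the excess sign,

    c₁ = (c_b + s·c_a)/2,   c₂ = (c_b − s·c_a)/2,
    ee = 100·(c₁ − c₂)/(c₁ + c₂).

**Signed inversion with a fitted intercept.** The CD curve is fitted to
L-enantiomer standards, so the signed estimate is d = (θ − intercept)/slope;
c_a = |d| and the excess sign is sign(d). This reconciles the absolute value
in the difference relation with a non-zero fitted intercept, and it makes
the constant part of the peak-extraction noise bias (see below) cancel
between calibration and inversion.

**Racemic tolerance.** If |d| < max(LOD, 10⁻⁹ mM) the sign is treated as
0 and the racemic split returned: a below-detection sign is noise, not
information.

**Infeasibility.** c_a > c_b would imply a negative concentration. The
default is a hard `InfeasibleMeasurementError` carrying both values,
because silent repair hides calibration inconsistency; an opt-in clip mode
(`clip_infeasible=True`) sets the minor component to zero and flags the
result.

**Uncertainty (optional, off by default).** First-order propagation from
the calibration residual standard errors: σ_ca = s_cd/|m_cd|,
σ_cb = s_lc/|m_lc|, σ_c1 = σ_c2 = ½·√(σ_ca² + σ_cb²). The benchmark tables
report no uncertainties, so this is opt-in.

## Calibration

Unweighted ordinary least squares on (concentration, signal) pairs
(≥ 3 points, ≥ 2 distinct concentrations), R² = 1 − SSE/SST, working range
set by the extreme standards. Weighted or nonlinear calibration is out of
scope. Detection limits use the signal-to-noise convention, LOD at S/N = 3
and LOQ at S/N = 10, converted to concentration via the slope:
LOD = 3σ/|m|, LOQ = 10σ/|m|. When no independent noise estimate is
supplied, σ defaults to the fit's residual standard error √(SSE/(n−2)).

The scalar CD signal of a spectrum is, by default, the signed ellipticity
at the grid point of maximum |θ| inside 190–220 nm (the amino-acid Cotton
window); exact ties resolve to the lowest wavelength. A fixed-wavelength
mode is available. LC peaks are integrated trapezoidally over a stated
time window after subtracting a baseline estimated as the mean absorbance
in caller-specified flanking windows (no windows → no subtraction).

Inverse prediction is (signal − intercept)/slope with the sign preserved;
results outside the working range or below LOQ are flagged (`in_range =
False`), never fatal — a quantified mixture difference is routinely below
the range of the single-enantiomer standards.

## The synthetic instrument

The simulator (`cdquant.simulate`) generates the data the analysis
assumes, so every stage is testable without instrument files:

* **CD**: each analyte's L-enantiomer is a sum of Gaussian Cotton bands in
  wavelength (a standard chiroptical band approximation; no line-shape
  information beyond that is modelled). The noise-free mixture signal at
  each wavelength is 3298·Δε_L(λ)·(c_L − c_D)·l mdeg — mirror rule built
  in — plus additive, homoscedastic, independent Gaussian noise.
  Default grid 185–260 nm at 0.5 nm.
* **LC**: a single Gaussian peak at the retention time whose area is
  `response_factor · (c_L + c_D)` mAU·min, independent of the L:D ratio
  (perfect co-elution), plus Gaussian noise. Default grid 0–8 min at
  0.005 min.
* **pH hook**: a scalar attenuation factor, exactly 1.0 on the pH 3–8
  plateau, ramping linearly to a configurable floor (default 0.35) at
  pH 1 and pH 12 and flat beyond. Band *shifts* with pH are deliberately
  not modelled.
* **Seeding**: one master seed per series; per-spectrum seeds derived with
  `numpy.random.SeedSequence.spawn`, so series reproduce element-wise.

**Bundled analytes.** Three fixtures named after Leu, Pro and Met. Their
main-band amplitudes are tuned so each analyte's peak-ellipticity
calibration slope (mdeg per mM at 1 cm) equals its published five-point
calibration slope (0.1927, 1.0363 and 0.1899 respectively) — a convenience
anchor giving realistic signal magnitudes, not a claim about true Δε
values. Retention times/widths and response factors are generic
reversed-phase values chosen once (Leu: 4.2 min, σ 0.12 min,
9.5 mAU·min/mM; Pro: 3.1, 0.10, 14.0; Met: 5.0, 0.14, 11.0).

**Default noise.** σ_CD = 0.02 mdeg and σ_LC = 0.2 mAU. No instrument
noise levels are published for this workflow; these values put a
five-point calibration series in the R² ≥ 0.999 regime that benchtop CD
instruments reach, which is the regime the reference measurements report.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: wavelength-dependent or heteroscedastic
noise, baseline drift, photomultiplier saturation, band shifts with pH or
solvent, chromatographic tailing or co-eluting interferents, and inter-day
calibration drift. Tests demonstrate correctness of the estimator under
its stated noise model, not robustness to instrument pathologies.

**A noise subtlety the design absorbs.** Extracting the max-|θ| point from
a noisy, nearly-flat peak region is biased upward by the maximum of several
noise draws (~2σ here). Because calibration standards and mixtures use the
same extraction rule, the bias is absorbed into the fitted intercept and
cancels in (θ − intercept)/slope. This is why the intercept is subtracted
before taking the absolute value.

## Benchmark-table replay

`cdquant.benchmarks` bundles two published benchmark tables (single
enantiomers of Leu/Pro/Met/Trp; L/D mixtures of Leu/Pro/Met at 60:40,
80:20, 20:80 and 55:45 from equal-concentration stocks) as plain data.
`validate_reference_tables()` recomputes every nominal mixture
concentration from its stock/ratio design and every relative-error cell as
100·|Exp − Cal|/Cal, rounded half-up to one decimal, and compares with the
printed value.

Arithmetic is done in `decimal.Decimal` on the printed two-decimal
values: binary floats mis-round ties (a true 6.25% evaluates to
6.2499…99 and would print as 6.2 where the table prints 6.3).

Two printed cells are internally inconsistent with their own Cal/Exp
pair — Pro single-enantiomer L (Cal 25.00, Exp 24.00: printed 4.2%,
formula gives 4.0%) and the Pro 32 mM 60:40 L component (Cal 19.20, Exp
19.30: printed 1.6%, formula gives 0.5%). They are carried as a frozen
errata list (`KNOWN_ERRATA`) with the formula's value; the validator
reports them rather than hiding them. The headline bounds hold either
way: mixture errors ≤ 10% (maximum 9.4%), single-enantiomer maximum 7.7%.

## Numerical and design choices

* Factor 3298 exact; peak tie-break to the lowest wavelength; slope
  magnitudes below 10⁻¹² treated as flat response; R² clamped to [0, 1].
* Published LOD/LOQ pairs for the reference analytes are *not* reproduced
  or asserted: they do not follow any single σ-based formula and their
  derivation is unstated. Only the S/N = 3/10 conversion rule is
  implemented.
* The Pro working range is taken from the extremes of the input standards,
  as for every analyte; no per-analyte overrides.
* Simulation sizes used by the test-suite statistics: 200 replicates for
  the Monte-Carlo recovery and R²-regime checks, 10⁴ pairs for the solver
  round trip, 10⁴ grid points for the noise-variance check. These sizes
  give comfortably small binomial/χ² fluctuation at the asserted
  thresholds.
* The acceptance script's calibration-quality figure is the *minimum* R²
  over 100 seeded five-point fits on the published L-Leu line with
  σ = 0.02 signal units — a conservative summary of the "at least 0.999"
  regime.

## Known limitations

Two co-eluting chiral species maximum (one analyte per mixture);
diastereomers and online LC-CD coupling are out of scope. The CD and LC
measurements are modelled as independent. Quantification accuracy is
bounded by the calibration working range: mixture differences far below
the standards' range are extrapolations and are flagged as such.
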