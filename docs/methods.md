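# Methods

This note records the models behind `gravical`, the defaults and their
rationale, what the virtual instrument does and does not emulate, and the
numerical and design choices made where the procedure left room.

## Calibration model

The command transform of a liquid-class subclass is affine, `Y = a·X + b`,
mapping target volume `X` (µL) to plunger volume `Y` (µL). The virtual
instrument's latent response is likewise affine: a commanded volume `Y`
delivers `p·Y + q` µL plus per-tip bias and noise. Composing the two, the
delivered volume is affine in the target with slope `p·a` and intercept
`p·b + q`; gravimetric measurement recovers this line (up to balance
quantization and noise), which is exactly what the adjustment stage fits.

Given the fitted line (slope `a₂`, intercept `b₂`) through the three
(theoretical volume, mean measured volume) points, the update is

    a_new = a₁ / a₂
    b_new = (b₁ − b₂) / a₂

applied to the working copy of the subclass, re-measured, and repeated until
all three volumes meet their accuracy limits or the attempt cap (default 4)
is reached. Properties of this update on a noiseless linear instrument:

- **Factor**: after one update, `a = 1/p` exactly — the slope is inverted in
  a single step regardless of the starting point.
- **Offset**: once `a = 1/p`, the update reduces to the scalar iteration
  `b ← (1−p)·b − q`, whose fixed point is `b* = −q/p` and whose error
  contracts by `|1−p|` per round. It converges iff `0 < p < 2` and diverges
  for stronger over-delivery; non-convergence is reported as a result state,
  never an exception.

The offset update is *not* the algebraically exact one-step inverse
(`b₁ − (a₁/a₂)·b₂`, which would reach `b*` immediately). We deliberately
implement the iterative form above because it is the established procedure
this package automates; in the practically relevant regime (`p` within a few
percent of 1) the iteration converges in one or two rounds anyway. A
consequence worth knowing: because the loop stops as soon as the *accuracy
criteria* are met, the persisted offset can sit anywhere inside the accuracy
band rather than at the exact fixed point — for subclasses with large
predefined offsets (e.g. 16–20 µL at 200–1000 µL) the residual systematic
error after calibration is bounded by the accuracy limit (≈0.5% of the
smallest test volume), not by the balance resolution.

Adjustment gates on accuracy only; confirmation (n = 16 per volume) gates on
accuracy *and* precision. Precision is driven by the pipetting parameters
(speeds, air gaps), which this workflow selects among predefined sets at the
screening stage but never tunes — hence there is nothing the adjustment loop
could do about a precision failure.

The regression orientation is x = theoretical volume, y = measured mean.
This orientation makes the factor update's fixed point the true inverse
slope; the reverse orientation would not.

## Statistics and acceptance criteria

`%DEV` is computed from the mean measured volume (accuracy *of the mean*),
signed in summaries and reports, compared as a magnitude against the limits.
`%CV` uses the sample standard deviation (n−1 denominator, the metrological
convention) over all tips and replicates of one volume. Both comparisons are
inclusive: a value exactly at its limit passes.

The built-in criteria grid is indexed by (subclass 1–3, volume 1–3) per
liquid class. Only the serum row is fully specified; DMSO covers subclass 2
and water subclass 2 plus the first cell of subclass 3. Missing cells
inherit the serum value at the same position — serum is the only complete
reference row — and everything is overridable through a criteria CSV.

Test volumes per subclass are `v1 = ceil(vmin)`, `v3 = min(floor(vmax),
cap)`, `v2 = round-half-up((v1+v3)/2)`. Half-up rounding (600.5 → 601,
700.5 → 701) matches how the midpoints are conventionally reported; the
default 900 µL cap keeps the largest test volume deliverable by a 1 mL
syringe together with its air gaps. Volume ranges are half-open
`[vmin, vmax)`: a printed shared endpoint such as 15.01 µL belongs to the
upper subclass. The vendor's own treatment of shared endpoints is not
documented; ours is a convention, chosen for uniqueness of selection.

## The virtual instrument

What it emulates:

- an affine true response (`p`, `q`) — the latent physics the factor/offset
  calibration inverts;
- eight fixed tips with additive per-tip volume biases;
- dispense noise with SD `sqrt((noise_cv·V)² + noise_floor_sd²)`: a
  proportional component and an absolute floor combined in quadrature, the
  floor dominating below roughly `noise_floor_sd / noise_cv` = 100 µL;
- an analytical balance with 0.1 mg readability (readings quantized), tare
  before every dispense, optional Gaussian read noise, and an optional
  linear evaporation loss (off by default; when on, `rate × settle_time` is
  subtracted from each dispensed mass).

Defaults `noise_cv = 0.004`, `noise_floor_sd = 0.4` µL are
reverse-engineered from the precision a well-maintained fixed-tip
workstation exhibits — %CV of roughly 0.2–0.5% at hundreds of µL and a few
percent at 3–16 µL; no direct noise measurement underlies them and both are
plain config keys. One RNG per instrument, seeded explicitly; within a run,
volumes are dispensed in order, replicates within a volume, tips 1–8 within
a replicate ("one tip at a time").

What it does not emulate — and what passing tests therefore cannot show
about real hardware: viscosity and surface-tension effects (why liquid
classes exist at all), air-gap fluid dynamics, carry-over between liquids,
aspiration-side errors, drift over time, air buoyancy, and draft/vibration
on the balance. The simulator answers "does the calibration *procedure*
converge and gate correctly given a linear instrument", not "is this
instrument linear".

## Assay analytics

**Langmuir capacity.** For adsorption `q = Cmax·K·c / (1 + K·c)` the
linearization `c/q = c/Cmax + 1/(K·Cmax)` is fitted by OLS with `x = c`
(µg/mL, supernatant concentration) and `y = c/q` ((µg/mL)/(mg/mg)); the
slope is `1/Cmax` with units (mg/mg)⁻¹, so the capacity `1/slope` carries mg
protein per mg adjuvant. Fits with R² ≤ 0.99 are flagged invalid; a
non-positive slope (no finite capacity) is an error. The synthetic isotherm
generator draws from the same forward model with optional Gaussian noise on
`q`; the linearization is exact on noiseless data, so round-trip recovery is
at machine precision. Note that OLS on the linearized coordinates is not
maximum-likelihood under noise on `q` (the transform `c/q` reweights
errors); at the few-percent noise levels relevant here the induced bias is
far below the fit's sampling scatter.

**Path-length correction.** Microplate wells have liquid-height-dependent
path lengths, normalized via the water near-infrared absorption band:
`corrected = (A280 − A320 − buffer) × ref_nir / (A975 − A900)`, where
`ref_nir` is the 975−900 nm difference of water at 1 cm. `ref_nir` is a
required configuration constant (instrument- and temperature-dependent),
not a hard-coded number.

**Kinetics.** The catalytic rate is the OLS slope of fluorescence vs time
(R² > 0.99 gate) minus the substrate-only background rate; relative surface
phosphophilicity divides by a reference-material rate (≡ 1).

**Plate statistics.** Per-group (plate, row or column) and pooled mean, SD
and %CV with sample statistics throughout. The packaged reference plates
are printed to 2 (capacities) or 1 (rates) decimals; statistics recomputed
from them can differ in the last digit from values computed on unrounded
raw data (e.g. an intra-run CV of 2.75% vs a reported 2.73%). The same
quantization limit applies to deviations recomputed from 0.1 µL-rounded
mean volumes: at 300 µL the recomputed %DEV can differ from one computed on
raw masses by up to 0.0167 points. Tests assert only what the printed
precision supports.

## Numerical choices

- Balance readings round to the nearest resolution multiple (ties to even,
  as `round()` does); readings are clamped at zero before volume conversion.
- OLS fits use `scipy.stats.linregress`; tests cross-check against the
  closed-form normal equations computed independently.
- Degenerate inputs raise typed errors (`RangeError`, `InvariantError`,
  `ConfigurationError`, `XMLFormatError` with the offending element path)
  rather than propagating NaNs.
- XML numeric attributes are serialized with `repr(float)`, so write∘read is
  the identity on the data model.
- Screening ties (exactly equal %CV, as with a noiseless instrument) break
  by smallest |%DEV|, then by input order; with distinct CVs the
  recommendation is independent of class order.
- Non-convergence of the adjustment loop and failed confirmation are result
  states with full per-attempt history, enabling the session driver to
  continue with remaining subclasses and aggregate failures.

## Problem sizes

The test suite and the acceptance script run entirely on the virtual
instrument at the workflow's native sizes: 8 tips, 1–2 replicates, 3 test
volumes per subclass, at most 4 adjustment attempts; screening probes 5
classes at 300 µL; Langmuir recovery uses 8-point isotherms over
475–750 µg/mL with 100 replicates in the noisy-recovery property. Everything
completes in seconds.

## Known limitations

- The instrument model is affine; real pipettors can be nonlinear at the
  extremes of a subclass range, which is precisely why ranges are split into
  subclasses. Calibrating a strongly nonlinear response with an affine
  transform leaves structured residuals this package will happily accept if
  they fit inside the accuracy band.
- No air-buoyancy correction is applied to masses, and evaporation is a
  crude linear loss.
- Per-tip acceptance is out of scope: gating uses pooled statistics only,
  so one biased tip can hide inside seven good ones at large n.
- The criteria grid assumes at most three subclasses and three volumes;
  classes with a single full-range subclass reuse the subclass-1 row.
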