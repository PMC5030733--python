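# gravical — gravimetric calibration of multi-channel liquid handlers

`gravical` implements the automated gravimetric calibration workflow used to
qualify fixed-tip robotic liquid handlers in biopharmaceutical formulation
labs, together with the downstream assay analytics such a platform feeds
(adjuvant adsorption capacity, kinetic surface phosphophilicity, plate
reproducibility statistics). Because the point of the package is the
calibration *procedure*, it ships a virtual instrument — an 8-channel
pipettor with a latent linear response plus an analytical balance with
finite readability — so the whole loop is testable and reproducible without
hardware.

## The problem and the model

A liquid handler maps a target volume *X* (µL) to a commanded plunger
volume through a per-liquid, per-volume-range *liquid class* transform

    Y = a·X + b

with factor *a* (slope) and offset *b* (µL, intercept). Performance is
judged gravimetrically: each tip dispenses onto a 0.1 mg analytical balance,
and the dispensed mass divided by the liquid density ρ (g/mL) gives the
actual volume *V_A*. Two statistics gate acceptance per target volume *V_O*:

    %DEV = (V_A − V_O) / V_O × 100          (accuracy, signed)
    %CV  = σ / x̄ × 100                      (precision across tips/replicates)

Calibration runs in three stages:

1. **Screening** — each predefined liquid class (water, serum, DMSO,
   ethanol, liquid system) dispenses a 300 µL probe once per tip; the class
   with the lowest %CV (ties broken by smallest |%DEV|) is selected.
2. **Adjustment** — for each subclass, three test volumes (range minimum,
   midpoint, maximum, capped at 900 µL) are dispensed once per tip. If any
   volume misses its accuracy limit, an ordinary least-squares line through
   (theoretical volume, mean measured volume) gives slope *a₂* and intercept
   *b₂*, and the working constants are updated as

       a_new = a₁ / a₂        b_new = (b₁ − b₂) / a₂

   and the round repeats (at most 4 attempts). On a linear instrument with
   true response *p·Y + q*, the factor update inverts *p* in a single step;
   the offset update iterates toward −q/p, contracting its error by |1 − p|
   per round (convergent for 0 < p < 2).
3. **Confirmation** — the adjusted subclass is re-measured with two
   replicates per tip (n = 16 per volume) and gated on accuracy *and*
   precision; only then is it persisted to the liquid-class XML.

The assay layer adds the linearized Langmuir isotherm (c/q = c/Cmax +
1/(K·Cmax), adsorption capacity Cmax = 1/slope, R² > 0.99 gate), kinetic
catalytic rates (background-subtracted fluorescence slope) and per-group /
pooled plate statistics.

## Worked example

Calibrate an aluminum phosphate adjuvant suspension (ρ = 1.025 g/mL) on a
virtual instrument that under-delivers by 5% with a 2 µL intercept and a
realistic noise model (`instr.cfg`):

```
p = 0.95
q = 2.0
noise_cv = 0.004
noise_floor_sd = 0.4
```

```
$ gravical run --liquid AP --density 1.025 --seed 7 --instrument instr.cfg \
      --out-xml AP_cal.xml --out-report AP_report.csv
selected class: serum
subclass 1: adjust ok (2 attempt(s)), confirm FAILED, persisted=False
subclass 2: adjust ok (2 attempt(s)), confirm ok, persisted=True
subclass 3: adjust ok (3 attempt(s)), confirm ok, persisted=True
calibrated class 'AP_serum' written to AP_cal.xml
```

Screening picked the serum class (lowest %CV at the 300 µL probe), each
subclass reached its accuracy targets within the 4-attempt budget, and the
two larger-volume subclasses confirmed and were persisted with their new
factor/offset. Subclass 1 (3–15 µL) converged on accuracy but failed the 3%
precision limit at n = 16 — the expected behavior at single-digit
microliters, where the absolute noise floor dominates; the command exits
with status 2 so pipelines can catch the partial failure. The CSV report
holds every stage's per-volume mean, min, max, signed and absolute %DEV,
%CV, and the factor/offset tried at each attempt.

The plate-statistics command reproduces the reproducibility numbers of the
packaged adsorption-capacity reference plates (12 isotherms per plate):

```
$ gravical plate-stats src/gravical/data/adsorption_capacity_plates.csv
          n   mean     sd cv_pct
group
Plate 1  12  4.357  0.120  2.751
Plate 2  12  4.267  0.180  4.213
pooled   24  4.312  0.156  3.626
```

i.e. intra-run capacities of 4.36 ± 0.12 and 4.27 ± 0.18 mg β-casein per mg
adjuvant and a pooled inter-run CV of 3.63%.

## Layout

- `gravical.liquidclass` — liquid-class data model, test-volume derivation,
  XML persistence
- `gravical.gravimetry` — mass↔volume conversion, balance model (resolution,
  tare, noise)
- `gravical.instrument_sim` — the virtual 8-tip instrument and protocol runner
- `gravical.qc_stats` — %DEV/%CV, volume summaries, acceptance-criteria engine
- `gravical.calibration` — screening, adjustment, confirmation, full sessions
- `gravical.assays` — Langmuir capacity, kinetic rates, plate statistics
- `gravical.cli` — the `gravical` command

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
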