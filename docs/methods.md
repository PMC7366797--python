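# Methods

## Quantities and model

A personal dosemeter worn on a phantom reports the personal dose
equivalent Hp(10) (mSv). The experiment relates this reading to the air
kerma Ka (mGy) delivered at the phantom position. The per-condition
**response** is

    B = reading (mSv) × CF (mSv/mSv) / Ka (mGy),

where CF is the dosemeter's calibration factor (below). Four dosemeters
of one type are irradiated simultaneously per run; the run's response is
the arithmetic mean of the four per-dosemeter responses. Spread across
the four is modelled as lognormal: `sd_log` is the sample SD (n−1
denominator) of ln B and the multiplicative 95% uncertainty factor is

    K = exp(1.96 × sd_log),

so ~95% of individual responses fall within [B_g/K, B_g·K] around the
geometric mean. With a single dosemeter no spread can be estimated and
`sd_log`/K are reported absent rather than 1.

### Calibration

The slab-phantom calibration run delivers Ka = rate × duration/3600
(10.5 mGy/h × 720 s → 2.10 mGy), converted to a reference Hp(10) with the
standard-condition coefficient c = 1.21 mSv/mGy (662 keV, AP), giving
2.541 mSv (displayed 2.54). CF = reference Hp(10) / reading. EPDs are
calibrated individually (one CF per device); GB and LB badges are
lot-uniform, so a single lot CF uses the mean of the four readings. EPD
displays are cumulative; run readings are increments of the display,
taken before calibration is applied.

### Isotropic-geometry synthesis

Isotropic exposure is approximated by rotational exposures about axes at
zenith angles 30–150°. Each angle represents a zenith band and is
weighted by the band's solid-angle fraction

    w(θ_lo, θ_hi) = (cos θ_lo − cos θ_hi)/2 = ∫ sin θ/2 dθ,

with bands 0–45, 45–75, 75–105, 105–135, 135–180° partitioning the
sphere (weights 0.1464, 0.2241, 0.2588, 0.2241, 0.1464; exactly summing
to 1). Two weight modes exist:

- `printed` (default): coefficients rounded to 3 decimals
  (0.146/0.224/0.259/0.224/0.146, sum 0.999, deliberately not
  renormalized). This mode reproduces the published table cells — the
  EPD 662 keV cell is a rounding-boundary case (0.82435 → 0.82 with
  printed weights, 0.8251 → 0.83 with exact weights).
- `exact`: full-precision weights; the ISO value is then a true weighted
  mean bounded by the rotational extremes. Use this for analysis.

The published ISO table is not explicit about how its uncertainty was
formed. When per-dosemeter responses are available, each dosemeter
position is synthesized across the five angles separately and the four
per-dosemeter ISO values are aggregated, so the ISO K reflects spread
*after* angle averaging — consistently smaller than single-angle K
values, as in the published table. When only per-angle means exist, K is
propagated assuming independent angles: sd = sqrt(Σ (w·sd_θ)²).

### Working-environment factors

Facility profiles give dose fractions over photon-energy bands (0–100,
100–300, 300–3000 keV) and geometries (AP, ISO, ROT). Presets: NPP =
(0, 0.10, 0.90) and MA = (0, 0.20, 0.80) over bands, both 50% AP / 50%
ISO. The 100–300 keV band is represented by the measured 119 and 207 keV
responses mixed 25:75; 300–3000 keV by the 662 keV point. The 0–100 keV
band carries zero weight in both presets and has no measured
representation; a profile giving it nonzero weight is rejected unless a
band mix supplies one (no extrapolation below 119 keV). The ROT class is
carried (weight 0 in the presets) so custom profiles can use the
measured 90° rotational row.

The published source does not state how its facility table aggregates
cells. Both options are implemented; the default is **log-scale**
(weighted geometric mean), for two reasons: it is the natural companion
of the lognormal uncertainty model, and on the published response table
it reproduces the published facility factors (EPD 1.00/1.01 and LB
1.06/1.08 exactly; GB 1.03 vs published 1.02, one display unit high —
whether the original was computed from rounded or full-precision inputs
is unknowable). Arithmetic aggregation is ≥ the geometric value (AM–GM)
and overshoots by 0.01–0.02 on these inputs; it is reported side by
side, never silently. K propagates as
sd = sqrt(Σ (w_cell·sd_cell)²) over the flattened
(energy, geometry) cells, assuming independence; on the published inputs
this lands on the published facility K values (1.004/1.003, 1.011,
1.037/1.033) to 3 decimals, which we treat as corroboration, not proof,
of the original procedure.

### Measurement error

The per-type measurement error is the SD of individual deviation rates
(r_i − mean)/mean from each run's mean reading, pooled across runs of
one type. Because each set's own mean is subtracted, a naive sample SD
of the pooled rates would be biased low by sqrt(1 − 1/n) (≈13% at
n = 4); the estimator therefore uses per-set degrees of freedom,
sqrt(Σ rates² / Σ(n_set − 1)), which is consistent for the per-reading
relative SD. Reference values: EPD 1.1%, GB 2.0%, LB 3.5%.

## Synthetic-data generator

The generator emulates the irradiation experiment, not dosemeter
physics: truths are table-driven, with no angular-response or transport
modelling.

- **Design**: the shipped 19-run plan — 1 slab calibration run plus
  3 energies (119/207/662 keV) × 6 geometries (AP, ROT at
  30/60/90/120/150°) — with 4 dosemeters of each of 3 types per run,
  printed dose rates and durations (reference kermas 0.91–2.41 mGy).
- **Truth**: the published per-condition mean-response table; the
  calibration condition uses the standard-condition response
  1.21 mSv/mGy, so generated calibration factors are near unity.
- **Noise**: multiplicative lognormal, reading = B·Ka·exp(ε),
  ε ~ N(0, sd%), with per-type defaults EPD 1.1 / GB 2.0 / LB 3.5
  percent. Multiplicative (not additive) noise matches the lognormal
  uncertainty model and guarantees positive readings; at these SDs the
  two are numerically indistinguishable. Position effects (surface
  inclination, distance per attachment point) are lumped into the
  per-type SD, as the source data do not separate components.
- **Rounding**: displays round to 0.01 mSv (half-to-even). EPD displays
  are cumulative: a per-device accumulator collects noisy doses run by
  run and each reading is the increment of the rounded display — exactly
  what differencing physical readings yields, including the ≤1-unit
  increment error.
- **Seeding**: one master seed; per-(run, type) substreams derive from a
  CRC-32 of the run id, so adding runs never perturbs existing ones.
  Identical seeds give bit-identical datasets.

What passing synthetic tests shows — and does not. The generator
contains the estimators' assumed error structure by construction, so
recovery tests validate the *estimators and plumbing* (no bias from
rounding at these kermas beyond ~half a display unit, correct pooling,
correct K coverage), not the physical adequacy of the lognormal model,
the absence of dose-rate or energy dependence, or any systematic
position effect in real data.

## Numerical choices

- Display rounding is half-to-even at 2 decimals (mGy/mSv tables) and 3
  (K), applied to the shortest decimal representation; all chained
  computation is full precision. The printed reference-kerma table is
  then reproduced in five of six cells; the N-150 AP cell computes 2.415
  and displays 2.42 against a printed 2.41 — a half-ULP edge tolerated
  at 0.01.
- The shipped design records 445 s with "11 rotations" for the N-250
  rotational runs, though 11 × 45 s = 495 s; the reference kerma is
  consistent with 445 s, so the duration governs and the inconsistency
  is surfaced as a warning, not resolved.
- Readings of 0 (below detection limit) are excluded from response
  computation with a warning; background contributes nothing at these
  delivered doses.
- Energies within ±2 keV are treated as the same nominal condition when
  matching legacy data (118/208 vs 119/207 keV band representatives).

## Problem sizes

Statistical checks run at deliberately desk-friendly sizes: ~1000
4-dosemeter sets for error recovery (sampling error ≈ 0.03 percentage
points on a 2% SD), 60 replicated 18-run experiments (≥1080 sets) for
K-band coverage, 10⁴ draws for generator self-checks. The whole suite
runs in a few seconds.

## Known limitations

- No interpolation of full conversion-coefficient tables; only
  user-supplied or shipped coefficients are used, so relative responses
  per Hp(10) at off-standard energies are out of scope.
- No modelling of instrument physics (filters, energy compensation,
  dead time, dose-rate dependence) or of beam divergence; parallel- vs
  divergent-beam deviations require transport simulation.
- Numeric legacy responses are not shipped (only the grouping); the
  legacy module operates on user-supplied values.
- The five-band zenith scheme *is* the isotropy model; no continuous
  angular interpolation between measured angles is attempted.
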