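# Methods

`altsense` models and analyses a coupled enzymatic assay for serum alanine
aminotransferase (ALT) activity in which ALT-generated pyruvate drives
pyruvate-oxidase (POX) reduction of ferricyanide:

```
alpha-ketoglutarate + L-alanine  --ALT-->  glutamate + pyruvate
pyruvate + phosphate + FAD       --POX-->  acetyl phosphate + CO2 + FADH2
2 Fe(CN)6^3- + FADH2             ----->    2 Fe(CN)6^4- + FAD + 2 H+
```

Ferricyanide consumption is the observable, read either as 420 nm
absorbance on a plate reader or as a baseline-current decrease on a
multiplexed array of nanowire field-effect sensors.  The package provides a
mechanistic simulator of both records plus the downstream analytics: trace
conditioning, rate extraction, calibration, detection limits, equivalence of
rate-reporting methods and interference assessment.

## Reaction model

The well state is (pyruvate P, ferricyanide F, ferrocyanide F') in µM,
integrated with an adaptive LSODA solver at fixed tolerances
(rtol 1e-8, atol 1e-10) so that the conservation property
`F + F' = F0` is a meaningful integrator check (enforced in tests to 1e-6
relative).

- **Pyruvate source.**  The ALT substrates (500 mM alanine, 15 mM
  alpha-ketoglutarate) sit far above typical Km values, so pyruvate
  production is zero-order: `v_eff = alt_activity × sample_fraction` µM/min,
  with `sample_fraction = 4/200` for a 4 µl sample injected into 196 µl of
  mixture.  1 U converts 1 µmol/min, so U/L of sample maps directly to
  µM/min in the well after dilution.
- **Pyruvate sink.**  POX is Michaelis–Menten in pyruvate with Km = 300 µM
  (a literature-typical placeholder, configurable) and Vmax derived from
  10 U/mL POX in the mixture (9800 µM/min in the well).  Because
  Vmax ≫ v_eff, pyruvate settles within seconds at a quasi-steady state and
  the ferricyanide depletion rate equals `2 × v_eff` (two ferricyanide per
  pyruvate via FADH2); this closed-form limit is the independent oracle for
  the integrator (2% agreement enforced whenever Vmax ≥ 100 × v_eff).
- **FAD/FADH2** are treated as instantaneously recycled: the terminal,
  rate-observed oxidant is ferricyanide itself, so no flavin pool enters the
  state.
- **Exhaustion.**  The POX rate carries a factor `F/(F + 0.1 µM)` so the
  reaction halts smoothly (and concentrations stay non-negative) when the
  ferricyanide pool runs out.

## Optical rendering

`A(t) = a_background + ε·l·[F](t) − drift·t + N(0, σ_read)`, sampled every
30 s.  Defaults: ε = 1040 AU·M⁻¹·cm⁻¹ at 420 nm, path length 0.57 cm (200 µl
in a 96-well plate), blank drift 1.1e-4 AU/s (the published blank rate of the
assay), read noise σ = 5e-4 AU (ordinary plate-reader noise; it puts the
scatter of replicate blank slopes over the 250–500 s window at ~2.6e-6 AU/s,
the same order as the published 4.4e-6 AU/s blank sd).  The absolute optical
gain implied by the published calibration CI cannot be reconciled with the
50-fold sample dilution and a 3.5 mM ferricyanide pool, so the simulator does
not force agreement with that CI: gains are configurable and calibration
quality is assessed through R², which is scale-free.

## Electrical rendering

Each sensor i of a die reports

```
I_i(t) = baseline_i + settle_i · exp(−t/τ) − gain_i · F'(t)/F0 − drift·t + noise
```

- The ferrocyanide term is linear (the array senses the converted charge
  fraction within a ~0.7 nm Debye length of the surface; a small-signal
  model is adequate over the ≤ 11% conversion reached in a 20-min record).
- The **settling transient** (default 40 nA, τ = 40 s) models the
  injection/flow disturbance that dominates the early raw record — the
  reason traces are offset to an equal baseline at 144 s before analysis.
  It is essential, not cosmetic: percent-full-scale rescaling divides each
  sensor's signal by its full-record range, and if every trace were affine
  in time the rescaled slope would be identical (100/record length) at every
  activity.  With a common-shape transient dominating the range, the %FS
  window slope becomes ≈ proportional to activity, which is what makes a
  rescaled calibration possible at all.
- **Die-level parameters.**  Baselines (800 ± 50 nA), gains (60 nA per unit
  converted fraction, 10% CV) and settling amplitudes (20% CV) are drawn
  once per dilution series and shared by all runs: a series is measured on
  one physical die whose sensors keep their characteristics across assays.
  Redrawing them per run would add ~8% multiplicative scatter to %FS rates,
  inconsistent with day-to-day-reproducible calibration on a single die.
- **Timing.**  Measurement cycles have period Normal(31.7 s, 0.12 s); each
  sensor is read in its multiplexer slot, 8 raw samples per cycle
  (σ = 0.06 nA each, ~0.02 nA after the boxcar), with the cycle index shared
  across sensors.

All randomness descends from one root `SeedSequence` on the configuration
seed; every (activity, replicate) entry gets its own child stream, so series
are bit-for-bit reproducible and entries statistically independent.

## Signal pipeline

Boxcar average per measurement cycle → per-sensor baseline offset at the
cycle nearest 144 s (no interpolation, ties to the earlier cycle) →
percent full scale, `%FS = (y − y_min)/(y_max − y_min) × 100`, with extrema
over the full record (a range ≤ 1e-9 signal units raises a degenerate-trace
error; blanks pass because drift and transient give them genuine range) →
ensemble mean ± sample sd (n−1) across the array at each cycle.  Averaging n
independent sensors shrinks the noise of the mean by √n (verified by Monte
Carlo at n ∈ {1, 4, 7, 16}).

## Rate extraction and calibration

Signals fall, so every reported rate is the magnitude of decrease (negated
OLS slope; the signed slope is retained).  Two reporting methods:

- **Fixed interval**: OLS over the closed window 250–500 s (optical) or
  300–460 s (electrical %FS ensemble).
- **Maximum slope**: among windows of consecutive cycles spanning ~160 s
  (point count = round(160/median period) + 1, six points at the nominal
  31.7 s cycle) lying fully inside 300–600 s, the steepest decrease wins;
  ties go to the earliest window.  This makes the reported rate independent
  of the exact assay start time.

Calibration is OLS of rate vs activity restricted to the linear range
50–450 U/L (the 0 U/L blank is excluded from the fit; 50 U/L is treated as
1× the upper limit of normal, with 3× and 8× the clinical monitoring and
stopping thresholds).  The 95% slope CI is t-based with n−2 df.  Detection
limits follow the standard definitions: LOB = mean blank rate + 3·sd;
LOD = 3·s/m with s the replicate sd at a low activity and m the calibration
slope.  Two calibrations are *equivalent* when their closed 95% CIs
intersect.  Interference is a significant slope change with an interferant
present, tested via the group×activity interaction term of a pooled OLS
(α = 0.05); identical series yield p = 1 by construction, and the test's
type-I error is verified to sit within 2 binomial sd of α over 1000 null
replicates.

## Problem sizes and numerical choices

Default synthetic experiments use 10 activities (0–450 U/L in 50 U/L
steps) × 3 replicates, 20-min records, 7 sensors — the scale of the original
dilution-series experiments; a full dual-modality generation plus
quantification runs in a couple of seconds.  Sliding-window ties are broken
with a 1e-12 relative tolerance so exactly-linear traces select the earliest
window.  CSV round trips write 17 significant digits and parse with
round-trip float precision.

## What the generator does and does not emulate

It emulates: rate ∝ activity over 50–450 U/L, blank drift, per-read optical
noise, per-sensor baseline/gain/settling variation, cycle-period jitter, and
full-record %FS normalisation effects.  It does not emulate serum-matrix
optics, pH dynamics (the serum is buffered), temperature drift, sensor
drift/aging, outlier sensors, or the absolute optical/electrical gains of
any particular instrument.  Passing tests therefore demonstrate the
correctness and calibration behaviour of the *analytics*, not instrument-
level accuracy on real serum data.
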