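# altsense

Simulation and analytics for a coupled enzymatic assay of serum alanine
aminotransferase (ALT) activity — the first-line blood marker for
drug-induced liver injury.  The assay couples ALT-generated pyruvate to
pyruvate-oxidase reduction of ferricyanide,

```
alpha-ketoglutarate + L-alanine  --ALT-->  glutamate + pyruvate
pyruvate + phosphate + FAD       --POX-->  acetyl phosphate + CO2 + FADH2
2 Fe(CN)6^3- + FADH2             ----->    2 Fe(CN)6^4- + FAD + 2 H+
```

so ferricyanide consumption reports ALT activity.  It can be read as a 420 nm
absorbance decrease on a plate reader or as a baseline-current decrease on a
multiplexed array of 7 nanowire field-effect sensors.  `altsense` is aimed at
assay developers and analysts who need a tested, reproducible implementation
of the full analytics chain:

- a mechanistic simulator of the coupled reaction rendered as optical traces
  and multiplexed sensor-array runs (seeded, bit-for-bit reproducible);
- tidy CSV I/O for plate-reader kinetic tables and sensor logs;
- the sensor signal pipeline: per-cycle boxcar averaging, baseline offset at
  144 s, percent-full-scale rescaling `%FS = (y - y_min)/(y_max - y_min) * 100`,
  and cross-sensor ensemble averaging;
- rate extraction (fixed-interval, and the start-time-independent maximum
  slope over ~160 s windows in 300-600 s), OLS calibration over the linear
  range 50-450 U/L with t-based 95% slope CIs;
- detection limits (LOB = mean blank + 3 sd; LOD = 3 s / m), CI-overlap
  equivalence of rate-reporting methods, and interference testing via a
  pooled-regression interaction term;
- a Debye screening-length utility for the electrostatic sensing range.

See `docs/methods.md` for the model, parameters and numerical choices.

## Worked example

Generate the default synthetic dilution series (0-450 U/L in 50 U/L steps,
3 replicates on one 7-sensor die), run the full pipeline and calibrate the
maximum-slope rates:

```python
import altsense as al

cfg = al.SimulationConfig(seed=1)
data = al.generate_dilution_series(modality="electrical", config=cfg)
rates = al.extract_series_rates(data, method="max")
cal = al.fit_calibration([(a, r.rate) for a, _, r in rates])
print(f"slope  = {cal.slope:.3e} %FS/s per U/L")
print(f"95% CI = [{cal.ci95_slope[0]:.3e}, {cal.ci95_slope[1]:.3e}]")
print(f"R^2    = {cal.r2:.4f}   (n = {cal.n})")
```

prints

```
slope  = 3.227e-05 %FS/s per U/L
95% CI = [3.138e-05, 3.315e-05]
R^2    = 0.9956   (n = 27)
```

i.e. the ensemble %FS rate rises linearly with ALT activity across the
clinically relevant range (1x-9x the 50 U/L upper limit of normal), and the
27 in-range points fit a line with R^2 = 0.9956.  The fixed-interval
(300-460 s) calibration on the same data gives an overlapping 95% CI
(`al.slopes_equivalent(...)` returns `True`), so reporting the maximum slope
— which does not require knowing the exact assay start time — is equivalent
to reporting a fixed-window rate.  The same session gives
`al.compute_debye_length() -> 0.78` nm for physiological ionic strength at
37 C, the distance within which the sensors see the converted charge.

The same chain is available from the shell:

```
altsense simulate --seed 1 --out runs/
altsense quantify runs/ --modality electrical --method both --out results/
altsense limits results/rates.csv --method max --out results/limits.json
altsense debye
```

Every output directory contains a `manifest.json` (command, seed, config,
package version) sufficient to regenerate the data bit-identically.

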