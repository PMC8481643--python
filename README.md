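# sorgspec

Chemometrics for grading sorghum grain as **food, feed, or fuel** from
FT-NIR absorbance spectra.

Sorting grain lots by end use requires knowing their starch, protein, fat,
tannin and structural-fibre (cellulose, hemicellulose, lignin) content, but
wet-chemistry assays — Kjeldahl nitrogen, acid hydrolysis, ether extraction —
are slow and destructive. Near-infrared spectroscopy replaces them with a
single non-destructive scan plus a multivariate calibration. `sorgspec`
implements that calibration workflow end to end for analysts building or
auditing such models:

- **I/O** for wide-format spectra CSV (rows = samples, columns = wavenumbers
  in cm⁻¹) and reference chemistry CSV (8 analytes, g kg⁻¹), with validation
  and sample-ID alignment.
- **Pretreatments**: multiplicative scatter correction (MSC), standard normal
  variate (SNV), Savitzky–Golay smoothing and derivatives, composable recipes
  such as `MSC+SG51p2d2` with calibration-state reuse on validation data.
- **Partitioning**: Kennard–Stone and SPXY deterministic 3:1
  calibration/validation splits (n_cal = ⌊3n/4⌋).
- **Wavelength selection**: competitive adaptive reweighted sampling (CARS)
  driven by |PLS regression coefficient| under an exponentially decreasing
  retention schedule, scored by cross-validated RMSE.
- **Outlier screening**: iterative removal of samples outside the χ²(2)
  confidence ellipse (95%) on the first two PCA score axes.
- **PLS regression**: single-response NIPALS with leave-one-out selection of
  the latent-variable count (2% parsimony rule), exposed both as functions
  and as a scikit-learn estimator (`NIPALSRegression`).
- **Performance metrics**: R² (squared Pearson correlation of predicted vs
  measured), RMSEc/RMSEcv/RMSEv, RPD = SD/RMSE, CV% = 100·SD/mean, paired
  t-test, and the standard adequacy tiers (RPD > 4 and R² > 0.95 →
  *efficient*, down to 1.75/0.7 → *preliminary*).
- **Composition & grading**: the acid-hydrolysis composition formulas
  (cellulose = 0.9·glucose, hemicellulose = 0.88·(xylose + arabinose),
  lignin = soluble + insoluble) and the threshold decision table
  (tannin ≥ 15 g kg⁻¹ → fuel; hemicellulose ≥ 50 → feed & fuel;
  starch ≥ 650 → food; else feed).
- **Synthetic study generator**: 98 samples (61 hulled + 37 hull-less) ×
  1,557 wavelengths over 4,000–10,000 cm⁻¹, drawn as Beer–Lambert Gaussian-
  band mixtures with mass closure, scatter/baseline/noise effects, and
  analyte distributions moment-matched to published descriptive statistics —
  so the whole pipeline is testable without instrument data.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

Calibrate a starch model on a simulated hulled-grain-flour study:

```python
import sorgspec as sg

dataset = sg.simulate_study(sg.StudyConfig(scan_format="hulled_flour", seed=42))
recipe, split_method = sg.DEFAULT_RECIPES["hulled_flour"]["starch"]
cell = sg.run_cell(dataset, "starch", recipe, split_method,
                   sg.PipelineConfig(), seed=42)
r = cell.report
print(f"PC={r.n_lv}  R2cv={r.r2_cv:.3f}  RPDcv={r.rpd_cv:.2f}")
print(f"validation: R2v={r.r2_val:.3f} RMSEv={r.rmse_val:.2f} "
      f"RPDv={r.rpd_val:.2f} rating={r.rating}")
```

prints

```
PC=7  R2cv=0.997  RPDcv=18.49
validation: R2v=0.996 RMSEv=4.55 RPDv=13.25 rating=efficient
```

Reading: the recipe `MSC+SG51p2d2` (MSC, then a 51-point second-derivative
Savitzky–Golay filter) was applied, the 61 samples were split 45:16 by SPXY
(one calibration outlier was screened out), CARS kept 44 of 1,557
wavelengths, and leave-one-out cross-validation chose 7 latent variables
("PC"). The validation RMSE of 4.55 g kg⁻¹ against a subset SD of ~60 g kg⁻¹
gives RPD ≈ 13, far above the RPD > 4 / R² > 0.95 bar for an *efficient*
model — as expected on low-noise synthetic spectra that satisfy the
calibration's own assumptions.

The same workflow is scriptable from the shell:

```bash
sorgspec simulate --seed 42 --out-spectra spectra.csv --out-reference chem.csv
sorgspec preprocess --recipe "MSC+SG51p2d2" --in spectra.csv --out treated.csv --state state.json
sorgspec split --method spxy --analyte starch --in treated.csv --ref chem.csv --out split.json
sorgspec pipeline --seed 42 --out report/      # full 4 formats x 8 analytes study
```

`sorgspec pipeline` writes `report/study_report.json`, a `summary.csv` with
one row per format × analyte (PC, R²c, RMSEc, SD, R²cv, RMSEcv, RPD, R²v,
RMSEv, RPD, SD, rating), and per-sample `grades.csv`.

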