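# Methods

`sorgspec` implements a complete FT-NIR calibration workflow for sorghum
grain composition — preprocessing, sample partitioning, wavelength selection,
outlier screening, PLS regression with cross-validated model selection,
adequacy metrics, and threshold grading — together with a synthetic spectra
generator that reproduces the statistical structure the workflow assumes.
This note records the models, the defaults, and the design choices made
where the design was genuinely open.

## Calibration workflow

For each scan format (whole grains, whole grain flours, hulled grain flours,
hull-less grain flours) and each of eight analytes (starch, protein, fat,
tannin, cellulose, hemicellulose, lignin, ash; g kg⁻¹):

1. **Pretreatment.** A recipe of scatter correction (MSC or SNV) followed by
   Savitzky–Golay smoothing/derivative. MSC regresses each spectrum on the
   calibration mean spectrum by OLS, x_i ≈ a_i + b_i·ref, and corrects to
   (x_i − a_i)/b_i; the reference is part of the fitted state, so validation
   spectra are corrected against the *calibration* mean. SNV centres and
   scales each spectrum to unit SD (n−1 denominator). The nominal 52-point
   smoothing window is realised as the nearest odd SG window, 51 points with
   a quadratic polynomial; derivatives are per index step, with edges handled
   by polynomial extrapolation of the terminal fits (`scipy.signal.savgol_filter`,
   `mode="interp"`). A Norris gap–segment derivative is available as an
   alternative operator but is not the default. Mean-centering is *not* part
   of a recipe; it happens inside model fitting. The per-cell default recipes
   (scatter method, derivative order, split method) are shipped as a packaged
   table (`sorgspec.pipeline.DEFAULT_RECIPES`).

2. **Partitioning.** Deterministic 3:1 calibration:validation split with
   n_cal = ⌊3n/4⌋ (98→73/25, 61→45/16, 37→27/10) by Kennard–Stone (maximin
   Euclidean distance on the treated spectra) or SPXY, whose joint distance
   d(i,j) = d_X/max d_X + d_y/max d_y also spans the response; with constant
   y, SPXY reduces to KS. Ties break to the lowest index. The split geometry
   is computed on spectra treated with a whole-set preprocessing state; the
   state used for *modeling* is then refit on the calibration subset only.

3. **Outlier screening** on the calibration subset: spectra are projected on
   the first two principal components, each score standardised by its SD, and
   a sample with T² = z₁² + z₂² above the χ²(2) quantile at 95% (5.991) lies
   outside the confidence ellipse. The single worst offender is removed, PCA
   is refit, and the loop continues until no sample is flagged or a cap (10
   by default) is reached; the screen never removes more than half the input.
   A per-axis rectangle variant is available behind a flag. Screening runs on
   calibration data only — screening before the split would mix validation
   information into the retained set and change the printed split sizes.

4. **CARS wavelength selection** on the screened calibration data. Each of
   N = 50 Monte-Carlo runs fits a PLS model on a random 80% of the
   calibration samples over the currently retained wavelengths; a forced
   reduction keeps the ⌈r_i·p⌉ wavelengths with the largest |regression
   coefficient|, where r_i = a·e^(−k·i) with a = (p/2)^(1/(N−1)),
   k = ln(p/2)/(N−1) (so r₁ = 1 and r_N = 2/p); adaptive reweighted sampling
   then resamples survivors with probability ∝ |coefficient| (a multinomial
   draw realised as the set of wavelengths drawn at least once). The retained
   set never drops below 2. Each run's set is scored by cross-validated RMSE
   of a PLS model (fixed component count, 10 by default) on the full
   calibration set; the full-wavelength set is recorded as the run-0
   baseline, so the winner never scores worse than using every wavelength.
   Inside CARS the cross-validation is 5-fold by default for speed; the final
   model selection is leave-one-out.

5. **PLS calibration.** Single-response NIPALS: with one response the weight
   vector has the closed form w = X′y/‖X′y‖, so each latent variable is
   extracted in one pass. X and y are mean-centered internally; coefficients
   are expressed on the original variables. The latent-variable count is the
   smallest candidate whose leave-one-out RMSECV is within 1.02× of the curve
   minimum (parsimony rule, tol = 2%), candidates up to 15.

6. **Metrics and rating.** R² is the squared Pearson correlation between
   predicted and measured (the convention of calibration-software scatter
   plots; 1 − SSE/SST is available behind a flag). RMSEc/RMSEcv/RMSEv are
   plain root-mean-square errors; RPD = subset SD / matching RMSE, with the
   cross-validation RPD using the calibration-subset SD. Adequacy tiers:
   efficient (R² > 0.95, RPD > 4), successful (> 0.9, > 3), satisfactory
   (> 0.8, > 2.25), preliminary (> 0.7, > 1.75), else inadequate; when the
   two indices disagree the lower tier is returned. A paired t-test
   (df = n − 1, two-sided) compares measured and predicted validation values.

7. **Composition and grading.** Cellulose = 0.9·glucose, hemicellulose =
   0.88·(xylose + arabinose) — the anhydro correction applied to the pentose
   sum, the standard reading of the assay — and lignin = acid-soluble +
   acid-insoluble. Grading thresholds (g kg⁻¹, boundaries inclusive):
   tannin ≥ 15 → fuel; tannin < 15 and hemicellulose ≥ 50 → feed_fuel;
   otherwise starch ≥ 650 → food, else feed. The feed_fuel branch is a
   reconstruction from the combined class's reported composition (its tannin
   minimum 13.85 < 15); the high-tannin/low-hemicellulose corner is not
   specified by the source grading scheme and is conservatively routed to
   fuel. All thresholds are configurable.

## Synthetic study generator

The generator emulates a 98-sample study (61 hulled + 37 hull-less grains)
scanned at 1,557 evenly spaced points over 4,000–10,000 cm⁻¹. The nominal
4 cm⁻¹ resolution would give 1,501 points; the printed variable count wins.

**Chemistry.** Each analyte is drawn from a normal truncated to the published
[min, max], with the parent moment-matched numerically so the *truncated*
distribution has exactly the published mean and SD (the published values are
empirical moments of bounded data). Independent analytes are sampled by
inverse CDF; an optional user correlation matrix switches to a Gaussian
copula with rejection on the joint box, where the marginal moments then hold
only approximately. For analytes whose SD approaches the uniform limit of
their interval (range/√12 — e.g. hull-less ash at 97% of it) the matched
truncated normal is nearly flat; that is the closest member of the family to
the published moments.

**Spectra.** Beer–Lambert forward model on the grid ν:

x_i = b_i·(Σ_a c_{ia}·s_a(ν) + m_i·s_mat(ν)) + a_i + t_i·(ν−ν̄)/(ν_max−ν_min) + ε_i

with pure-component spectra s_a built from 2–5 Gaussian bands at fixed,
documented centres in the 4,000–9,000 cm⁻¹ absorption region, globally scaled
so a mean-composition mixture peaks at 0.38 AU (matching the reported
0.25–0.43 AU absorbance range). The residual matrix term m_i = max(0, M − Σ_a c_{ia})
with M = 1,600 g kg⁻¹ completes each sample to a fixed total mass (moisture,
soluble sugars, other dry matter, with broad water-like bands at 25% of the
analyte absorptivity scale). Mass closure is the physical constraint that
makes absolute concentrations recoverable from scatter-normalised spectra:
without it, row-normalisation (SNV, MSC) destroys the overall-scale
information and no linear model can return g kg⁻¹ values. The clean mixture
remains affine in the eight concentrations, so the noise-free forward model
is exactly rank-8 after centering and an 8-component PLS model recovers any
analyte with R² = 1. A matrix-free library gives the pure linear mixture.

**Effects.** Multiplicative scatter b_i ~ 1 + N(0, 0.15²) (clipped > 0.1),
additive offset a_i ~ N(0, 0.02²) AU, linear tilt t_i ~ N(0, 0.02²) AU over
the grid, i.i.d. noise ε ~ N(0, (5·10⁻⁴)² AU) by default. Whole-grain scans
double the scatter/offset/tilt spreads relative to flours (hull and
particle-size scattering is why scatter correction is needed at all). The
5·10⁻⁴ AU default noise is typical of a 64-scan benchtop FT instrument; the
near-noiseless recovery checks use 10⁻⁵ AU.

**What the generator does not emulate:** instrument line-shape, wavelength-
dependent noise, temperature/moisture interactions, analyte cross-
correlations (identity by default), and real band assignments — the band
centres are plausible defaults, not claims. Passing the recovery suite shows
the workflow is correct and self-consistent on data satisfying its own
assumptions; it does not certify accuracy on real spectra.

## Numerical choices

- NIPALS stops early if the response residual is orthogonal to the spectra
  residual (norm < 10⁻¹⁴); PLS1 needs no inner iteration.
- MSC raises when a fitted slope |b_i| < 10⁻¹²; SNV raises on constant rows;
  both name the offending sample.
- Split ties (duplicate rows) resolve to the lowest index, never an error.
- Problem sizes in the test and acceptance suites: the full study (98
  samples, 1,557 variables, 32 format × analyte cells) runs in a few seconds
  per noise level; the CARS benchmark uses 150 samples × 200 variables with
  10 informative ones at SNR 20, 20 seeded repetitions.
- With 10-sample validation subsets (hull-less cells), the validation R² of
  an essentially exact model is itself a noisy statistic; under some seeds a
  single cell can dip slightly below 0.95 even at negligible noise.

## Known limitations

- The four-way grade counts of the original 98-sample set are not
  reproducible: they require the undeposited per-sample chemistry table.
- The grading decision for tannin ≥ 15 with hemicellulose < 50 g kg⁻¹ is a
  package choice (fuel), not a published rule.
- Published CV/RPD cells recompute from their printed rounded inputs only to
  ±0.01 in some cells; the arithmetic suite asserts the cells that round
  cleanly.
- Commercial-software numerics (exact R² convention, Norris parameters) are
  unverifiable; the alternatives are exposed behind flags.
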