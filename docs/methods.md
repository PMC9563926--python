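# Methods

## Scope and model

`breathflow` implements a targeted validation workflow for exhaled-breath
biomarkers of obstructive sleep apnea (OSA) measured by secondary
electrospray ionization high-resolution mass spectrometry (SESI-HRMS).
A subject's measurement is a time series of full positive-mode MS1 scans
(m/z 50–500 Da, 0.5 s accumulation) covering six consecutive exhalations;
the analysis reduces each session to one averaged breath spectrum, builds
a cohort intensity matrix, matches it against a fixed panel of previously
reported marker m/z features, and evaluates the panel by nonparametric
group statistics and cross-validated classification.

## Spectral preprocessing

1. **Recalibration.** Every session is mapped onto one reference breath
   spectrum (by default the first subject's most intense scan) with a
   two-parameter linear correction `m/z' = a·m/z + b`. Calibrants default
   to the protonated water-cluster series ([(H2O)2+H]+ 37.0284,
   [(H2O)3+H]+ 55.0390, [(H2O)4+H]+ 73.0495) because these ions are
   always present in breath; each calibrant is located as the
   intensity-weighted centroid of the signal above half the window apex
   in a ±0.02 Da search window, and the line is fitted by least squares.
   A linear model is used because TOF mass drifts are locally linear over
   50–500 Da and higher orders are unidentifiable from two or three
   calibrants. Fits with slope outside [0.999, 1.001] or |offset| >
   0.05 Da are rejected as implausible for a high-resolution TOF. For
   planted drifts up to ±0.01 Da the post-correction calibrant residuals
   are below 5·10⁻⁴ Da.
2. **Gridding.** Spectra are linearly interpolated onto a uniform common
   axis (default step 0.001 Da, about half the narrowest expected peak
   width at m/Δm ≈ 30,000); intensity outside a spectrum's support is 0.
3. **Exhalation gating.** A scan counts as a breath scan iff its maximum
   intensity within 55.039 ± 0.005 Da (the protonated water trimer)
   exceeds 10 % of the session-wide maximum of that window. The relative
   threshold makes the gate invariant to inter-subject intensity scale;
   for clean data it reduces to a simple on/off detector. Zero selected
   scans raise an error — that is a failed measurement, not an empty
   result.
4. **Averaging and peak picking.** The gridded breath scans are averaged
   first and peaks are picked on the mean trace (average-then-pick; the
   pick-then-average alternative is available behind a flag and agrees
   on clean data). A peak is a local maximum strictly above both
   neighbours (plateaus resolve to their midpoint) with apex ≥ 5
   counts/s — the height filter is a closed bound, so an apex of exactly
   5.0 passes. The centroid is the intensity-weighted mean m/z over the
   contiguous region above half the apex.
5. **Alignment.** Subject feature lists are clustered along m/z by 1-D
   single linkage, splitting wherever the gap between consecutive sorted
   features exceeds the 0.005 Da tolerance (the same tolerance used for
   panel matching). In one dimension this is exactly single linkage at
   that cut height; chains can in principle stretch a cluster beyond the
   tolerance, but at breath-peak densities this does not occur in
   practice. A subject lacking a cluster's feature gets intensity 0 —
   absent signal, not a missing value. The cluster representative m/z is
   the intensity-weighted mean.
6. **Normalization cascade.** Raw → TIC-normalized (each row divided by
   its total ion current, i.e. the sum of its picked peak heights) →
   median-scaled (all rows multiplied by the median TIC of the cohort,
   restoring a common intensity scale) → auto-scaled (per-feature
   z-score). Auto-scaling uses the population (n) standard deviation by
   default (`ddof=1` optional); zero-variance columns are dropped with a
   warning. The TIC-normalized matrix is retained alongside the z-scores
   because fold changes are ratios and are meaningless after centering.

## Marker panel and mass audit

The targeted panel is a fixed list of positive-mode m/z features. Each
matrix feature match is the nearest column within 0.005 Da (nearest
wins when two columns fall inside the tolerance). Panel entries carrying
an elemental composition are interpreted as cation formulas (protonated
species, charge +1); the bundled audit recomputes each composition's
monoisotopic m/z as the sum of most-abundant-isotope masses (IUPAC
values for C, H, N, O, S) minus one electron mass and checks agreement
with the printed value at the same 0.005 Da tolerance. All nine
attributed panel entries pass with deviations below 0.001 Da, which is
what justifies the charge-+1 reading.

The shipped 78-row panel contains the nine attributed markers (m/z,
composition, and names for 2-butylfuran and 4-(hexyloxy)phenol); the
remaining 69 m/z values are synthetic placeholders standing in for the
unpublished remainder of the reference panel, flagged per row in the
asset file. Analyses that depend on attributed chemistry use only the
nine-row panel.

## Stratification and statistics

Two inclusion rules are implemented. Stratification 1 keeps all
untreated subjects and keeps treated subjects iff averaged CPAP usage is
at least 5 h/night (closed bound: 5.0 passes, 4.9 fails).
Stratification 2 keeps a subject iff AHI > 30, or AHI > 10 and ESS > 10
(both bounds strict), with treated subjects additionally required to
meet the CPAP criterion; the AHI source is the visit value for untreated
subjects and the diagnostic pre-treatment value for treated subjects.
Controls pass unconditionally — the screening comparison uses the whole
control group. Legacy ODI-based variants of the severity criterion are
available behind `use_odi=True`. Subjects missing a required field are
excluded individually with a logged reason.

Marker testing uses the two-sided Mann–Whitney U test (reported U is
min(U₁, U₂); exact permutation p when n₁+n₂ ≤ 12 and the pooled sample
is tie-free, otherwise the normal approximation with tie and continuity
correction). Breath intensities are right-skewed, and the Shapiro–Wilk
p per group is reported as the normality gate that motivates the
nonparametric choice — it never switches the test silently. Because
auto-scaling is a strictly increasing affine map per feature, the rank
test gives identical p on the auto-scaled and TIC-normalized scales
(asserted in the test suite). Fold change is the ratio of group medians
on the TIC-normalized scale; direction is "increased" iff FC > 1.
Significance is unadjusted p < 0.05 by default; Benjamini–Hochberg
adjustment is available behind a flag but off by default, mirroring the
workflow being validated.

## Classification

Detected-marker intensities feed a linear soft-margin SVM (unit cost; no
hyperparameter search, since none is part of the validated protocol) in
stratified 10-fold cross-validation. AUC is computed per fold from the
decision values by the rank statistic (ties ½, equal to U₁/(n₁·n₂)) and
averaged over folds; the confusion matrix is pooled over folds at the
default margin-sign operating point, from which accuracy, sensitivity
(recall on untreated OSA) and specificity follow. Auto-scaling moments
are recomputed inside each training fold and applied to the held-out
fold, which avoids information leakage from test subjects into the
scaler; `paper_mode=True` reproduces the simpler global-scaling protocol
for comparison. `balanced_subsample` down-samples the majority class
uniformly at random (without replacement, deterministic per seed) to the
minority size before model building. Reports are reproducible bit for
bit from (matrix, labels, seed, config).

## Synthetic cohorts

The generator emulates the features of a breath-measurement cohort the
pipeline is sensitive to, with known ground truth:

- **Scan streams.** 3 ambient lead-in scans, then six exhalation blocks
  of 4 scans separated by 3 ambient scans (45 scans of 0.5 s). During
  exhalation the water-cluster series bursts with a trapezoidal profile
  (half-height shoulders); ambient scans carry 2 % background and no
  water-cluster signal. Peaks are Gaussian in m/z with width from
  m/Δm = 30,000. Spectra are stored as sparse profiles (half-sigma local
  grids to ±4σ per peak plus a 1 Da baseline lattice); additive Gaussian
  noise (default 1 count/s) and a per-subject mass offset drawn uniformly
  from ±0.003 Da complete the acquisition model. Points outside the
  configured acquisition range are not recorded.
- **Intensity model.** Marker intensities are log-normal across subjects
  (median 30 counts/s, log-SD 0.5) — right-skewed like real breath data,
  which is what makes the nonparametric testing appropriate. A planted
  effect of *e* pooled SDs adds *e*·SD(log-normal) to the untreated
  group's intensities for that marker; defaults plant the nine
  attributed markers at 2 pooled SDs, a clearly detectable signature.
  Baseline (non-marker) peaks are log-normal with median 20 counts/s and
  log-SD 1.
- **Metadata.** AHI/ODI/ESS are drawn from log-normal approximations
  fitted to the published group medians and interquartile ranges (e.g.
  untreated visit AHI median 28, treated 1.3); treated CPAP usage is
  normal(5.8, 1.5) h/night clipped at 0, so roughly two thirds of
  treated subjects meet the 5 h/night criterion and the stratification
  rules have non-trivial pass/fail sets.
- **Two tiers.** `generate_cohort` renders full scan streams to mzXML and
  exercises the entire spectral chain; `simulate_feature_matrix` draws
  the subjects × features matrix directly from the same intensity model
  for the large statistical simulations. The null-calibration suite runs
  1000 seeds at the stratification-1 group sizes (43 vs 29) with a
  42-feature panel; recovery and permutation suites run 200 seeds at the
  balanced 15 + 15 design; scan-level tests use cohorts of 2–32 subjects
  over a reduced acquisition window (50–210 Da) that covers every
  attributed marker.

What the generator does **not** model: ion-chemistry matrix effects,
instrument-specific noise spectra and drift dynamics within a session,
isotope patterns and adducts, correlated metabolite panels, and any real
association between metadata and breath chemistry (group labels drive
marker shifts directly). Passing tests therefore demonstrate that the
pipeline recovers what it is designed to recover under its own model
assumptions — not that the clinical effect sizes themselves are
reproduced. The published cohort-level numbers (42/78 detected features,
nine significant markers, AUC 0.80 at balanced n = 15) depend on patient
data available only on request and serve as design references, not as
test expectations.

## Numerical choices and edge cases

- Peak apex heights on a 0.001 Da grid are attenuated by up to ~4 % for
  TOF-width peaks (chord interpolation near the apex); tests use a 5 %
  tolerance on recovered heights and 0.001 Da on centroids.
- `interpolate_to_grid` preserves Gaussian peak area within 1 % for grid
  spacing at or below the native spacing.
- Ties in ROC scores contribute ½; ties in Mann–Whitney use midranks.
- Zero TIC raises an error naming the subject; zero-variance features
  are dropped with a warning before auto-scaling.
- Matching when the matrix has no columns is an error; an empty peak
  list is a valid picking result.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and configuration give
  bit-identical matrices and reports.

## Known limitations

- mzXML is the only on-disk spectral format (mzML and vendor formats are
  out of scope); MS2 scans are ignored.
- The exhalation-gate "presence" threshold (10 % of the session maximum)
  and the trapezoidal exhalation profile are modeling choices; real SESI
  intensity dynamics within an exhalation are not published for this
  workflow and both are configurable.
- Correlation of marker intensities with OSA severity indices and
  chemical identification of markers are out of scope.
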