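# Methods

## Design

The package models a cold-storage shelf-life study: fruits are sampled on
days 1, 4, 6, 8 and 11 (12 replicates per day) and characterized by surface
photographs, physicochemical and spectrophotometric measurements, and
ATR-FTIR spectra. The analysis treats replicates as independent; no
repeated-measures structure is modeled, because each sampled fruit is
destroyed by the measurements.

Two granularities of image analysis coexist: ROI-level (each 15×15 region
is a sample; 12 fruits × 8 ROIs = 96 samples per day) and fruit-level (the
8 ROIs are averaged; 12 samples per day). Both are supported —
`pipeline.extract_feature_table` produces ROI rows and
`pipeline.aggregate_per_fruit` collapses them — and analyses must state
which they use; the classifier and regression examples use fruit-level,
the texture day-contrast test uses ROI-level.

## Texture features

Definitions are the classical Haralick/Galloway forms, with conventions
fixed so every value is exactly reproducible:

- Grayscale conversion is ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B);
  quantization is uniform binning, q = ⌊v·G/256⌋ with G = 16 by default
  (power-of-two binning of 8-bit data; configurable).
- First-order moments are population moments on the unquantized patch;
  kurtosis is Pearson (non-excess); a constant patch has skewness =
  kurtosis = 0 by convention. "Energy" is the first-order histogram
  uniformity of the quantized patch; "angular second moment" is the
  co-occurrence analogue — they are distinct features.
- The co-occurrence matrix accumulates distance-1 pairs in four directions
  (0°, 45°, 90°, 135°), symmetrized, then normalized — a rotation-robust
  default. Correlation is 0 by convention when a marginal is degenerate.
- The run-length matrix accumulates maximal runs along horizontal and
  vertical scans; total pixels count once per direction so the run
  percentage stays in (0, 1].

These choices make the features brute-force verifiable: the test suite
checks the vectorized implementations against naive enumeration of pixel
pairs and runs on random patches to 1e-9.

## Color

Per-ROI color is the mean of per-pixel CIELAB values (not the Lab of the
mean RGB), computed with sRGB companding under the D65/2° reference white.
ROI selection supports manual coordinates, a deterministic raster grid, and
seeded uniform rejection sampling (the default; the seed is part of the
provenance output). Coordinates are 0-based, half-open.

## Statistics

- Mann–Whitney U uses the exact permutation distribution when the pooled
  sample has ≤ 16 tie-free values, otherwise the normal approximation with
  tie and continuity corrections. Two identical constant samples return
  p = 1 with a degenerate flag. Calibration: at n = 50 per group the null
  rejection rate at α = 0.05 is computed by the acceptance script over
  10,000 simulations; 50 per group was chosen because the statistic is
  discrete and intrinsically conservative at the study's n = 12, where the
  rejection rate reflects the continuity correction rather than the
  implementation.
- Consecutive-day comparisons report raw p-values by default (Holm
  adjustment behind a flag), matching the practice of reporting each
  feature's day-to-day changes individually.
- The post-hoc test after one-way ANOVA is Tukey HSD; the full pairwise
  p-matrix is exposed so another procedure can be substituted. The compact
  letter display uses the insert-and-absorb algorithm; its defining
  invariant — two groups share a letter iff their pairwise p ≥ α — is
  property-tested against random significance patterns. When every group
  has zero within-group spread, F is undefined and letters are assigned by
  mean ordering.
- Assay correlations are Pearson on the pooled rows by default (Spearman
  and group-wise computation behind flags). Pooled correlations include the
  between-day trend component and are therefore larger than the within-day
  noise correlation.
- Taste acceptability: TA ≤ 0.8 % citric-acid equivalents and TSS ≥ 7 °Brix,
  both required.

## Spectra

Band intensity defaults to peak height (maximum absorbance) within the
labeled window, with the window mean as an option. The 17 default windows
span 523–3645 cm⁻¹; three single-peak labels (3380, 1105, 523 cm⁻¹) carry
no width and are given ±5 cm⁻¹ windows (the grid step is 2 cm⁻¹, so each
window holds several points). No baseline correction is applied by default;
a linear endpoint-to-endpoint subtraction is available. Bands absent from a
spectrum's range produce missing cells, never zeros.

## Chemometrics

- Standardization: zero mean, unit population SD per column.
- PCA keeps two components with a deterministic sign convention (the
  largest-magnitude loading of each component is positive), so repeated
  runs are bitwise identical.
- Cross-validation is stratified repeated K-fold, 5 folds × 10 repeats by
  default. Stratification protects the 12-member day classes from empty
  folds; plain repeated K-fold is available via `stratified=False`.
  Standardization and the PCA projection are refit inside each training
  fold. Out-of-fold predictions are pooled over all repeats into per-class
  correct counts, so the overall accuracy is exactly the pooled "n of m"
  arithmetic. Classifiers train in PCA-2 space by default (decision
  surfaces are then exact); `use_pca=False` trains in full feature space.
- The gradient-boosting regressor uses 500 trees, depth 3, learning rate
  0.05, squared loss — fixed, not tuned — and is scored by pooled
  out-of-fold R². At the study's fruit-level sample size (n = 60) this R²
  is noticeably seed-dependent; the acceptance script reports the value at
  the seed it is given.
- Subset search enumerates all feature subsets up to the requested size
  (capped at 30 features) and scores each with one classifier's
  cross-validated accuracy.

## Synthetic data

The generator is a pure function of `SyntheticConfig`; one master seed
fixes every image, table row and spectrum, which the tests verify
byte-for-byte.

- **Images.** A Gaussian white-noise field is smoothed with the day's
  correlation length (5 → 2 px from day 1 to day 11), normalized, scaled to
  the day's intensity moments, and dark achene-like speckles are stamped
  in. The relative intensity field then modulates a base RGB color obtained
  from the day's CIELAB target with per-fruit jitter (SD 1.5 per Lab
  coordinate). Shorter correlation length yields higher co-occurrence
  contrast and more short runs — the signature of an aging surface. The
  default image is 192×256 px, large enough for eight non-overlapping
  15×15 ROIs while keeping full-study runs fast.
- **Measurement table.** Per-day normal draws around anchors. Hue,
  firmness, adhesiveness and cohesiveness anchors (means and SDs) are the
  published per-day values for this storage design; the remaining
  measurements use anchors reproducing the reported qualitative
  trajectories — soluble solids jump between days 4 and 6 and then
  plateau, acidity peaks on day 6 and is lowest on day 11, ascorbic acid
  dips on day 4 and recovers on day 6, the antioxidant assays peak on
  day 6 — with SDs of roughly half the day-to-day steps reported as
  significant. TPC/ABTS/FRAP share a latent noise component so their
  within-day correlation is 0.8.
- **Spectra.** Gaussian peaks centered in each of the 17 band windows, with
  per-day amplitude anchors equal to the published band-intensity table
  (two unmeasured cells filled with the band's mean over measured days),
  plus white noise (SD 5·10⁻⁴) on a 4000–500 cm⁻¹ grid at 2 cm⁻¹ steps
  (1751 points).

What the generator does **not** emulate: real lesion/mold morphology,
specular highlights and achene geometry, camera noise and JPEG artifacts,
FTIR baseline drift and atmospheric bands, and any dependence between a
fruit's image features and its chemistry beyond the shared day effect.
Passing the recovery tests therefore shows the pipeline detects the planted
storage-day structure at the study's sample sizes — not that real
strawberries are classified at these accuracies.

## Numerical conventions and degenerate inputs

- GLCM of a patch smaller than every offset's reach is an error; a constant
  patch gives contrast 0, homogeneity 1, ASM 1, correlation 0.
- A run-length matrix with zero runs is an error (cannot occur for a
  non-empty patch).
- Zero-variance columns are rejected by standardization (named in the
  error) and reported as missing by correlation.
- Band windows with no grid point raise an error naming the band.
- Synthetic band amplitudes are clipped at zero (absorbance cannot be
  negative in this model).

## Known limitations

- ROI placement is uniform; there is no content-aware avoidance of
  speckles or highlights (the real study placed ROIs manually).
- The letter display is the insert-and-absorb construction; it is valid
  (share iff non-significant) but not guaranteed to use the minimum number
  of letters in pathological significance patterns.
- Exhaustive subset search is combinatorial; beyond ~15 features with
  subset sizes > 3 it becomes slow, and beyond 30 features it refuses.
- The acceptance quantities computed on synthetic data (three-class
  accuracy, regression R², pooled assay correlations) are stochastic at
  n = 12 fruits per day and vary by a few points across seeds.
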