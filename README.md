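# berrylife

Shelf-life chemometrics for perishable fruit, built around the strawberry
cold-storage setting: surface photographs, physicochemical and antioxidant
assays, and ATR-FTIR spectra are collected on storage days 1, 4, 6, 8 and 11
(12 replicate fruits per day) and integrated into per-day statistics,
PCA-based discriminant analysis of the storage day, and regression
prediction of the storage day itself.

## What it computes

**Image texture and color.** Eight non-overlapping 15×15-pixel regions of
interest per photograph, each reduced to 18 features:

- first-order grayscale statistics — mean, population SD, skewness,
  Pearson kurtosis, histogram energy Σᵢ p(i)²;
- gray-level co-occurrence (Haralick) features on the quantized patch —
  contrast Σ(i−j)²P(i,j), homogeneity ΣP(i,j)/(1+(i−j)²), correlation,
  dissimilarity Σ|i−j|P(i,j), angular second moment ΣP(i,j)²;
- gray-level run-length (Galloway) features — short-/long-run emphasis
  (SRE, LRE), gray-level and run-length non-uniformity (GLN, RLN), run
  percentage (RP = runs/pixels);
- mean CIELAB color (L\*, a\*, b\*) of the ROI (sRGB → XYZ → Lab, D65/2°).

**Statistics.** Mann–Whitney U tests between consecutive days (exact
permutation p for small tie-free samples), one-way ANOVA with Tukey HSD
summarized as compact letter displays, pairwise Pearson/Spearman assay
correlations, and the taste-acceptability rule (titratable acidity ≤ 0.8 %
and total soluble solids ≥ 7 °Brix).

**Spectra.** Peak heights (or means) in 17 diagnostic FTIR wavenumber
windows between 523 and 3645 cm⁻¹, tabulated per day with Tukey letters.

**Chemometrics.** Standardization → 2-component PCA → a roster of ten
classifiers (nearest centroid, naïve Bayes, k-NN, LDA, logistic regression,
perceptron, MLP, random forest, decision tree, SVM) scored by repeated
stratified K-fold with pooled out-of-fold per-class counts; exhaustive
feature-subset search; decision-surface grids on the PCA plane; and
gradient-boosted regression of the storage day with pooled out-of-fold R².

**Synthetic data.** `berrylife.synthetic` generates the whole study —
images whose texture correlation length shrinks and color drifts with
storage, measurement tables following the observed per-day trajectories,
and spectra with day-dependent band amplitudes — as a pure function of one
master seed, so every pipeline stage is testable end to end.

## Worked example

```bash
python examples/05_classify_storage_days.py
```

discriminates storage days 1/6/11 from inner-surface lightness (L\*) and
the FRAP antioxidant assay (12 fruits per day, seed 1):

```
classifier leaderboard (pooled repeated 5-fold accuracy):
  naive_bayes           92.8%   (day 1: 120/120, day 6: 100/120, day 11: 114/120)
  nearest_centroid      92.8%   (day 1: 111/120, day 6: 110/120, day 11: 113/120)
  lda                   92.5%   (day 1: 117/120, day 6: 100/120, day 11: 116/120)
  ...
best: naive_bayes at 92.8%; decision surface computed on a 76 x 107 PCA-score grid
```

Each line pools the out-of-fold predictions of 10 repeats of stratified
5-fold CV (hence 120 = 12 fruits × 10 repeats per class); the overall
accuracy is the pooled correct fraction. Day 6 is the hardest class — its
lightness overlaps day 1 and its FRAP peak is transient. The other examples
cover dataset simulation, per-ROI feature extraction, day statistics, the
FTIR band table and storage-day regression (out-of-fold R² = 0.868 at
seed 1).

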