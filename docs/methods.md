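# Methods

This note records the models, parameter choices and numerical
conventions behind `pcnir`, and what the synthetic-data experiments do
and do not demonstrate.

## Synthetic data generator

Real NIR spectra of the 138-sample three-region *Poria cocos* study are
not publicly deposited; only regional summary statistics, band
positions and headline model metrics are published. The generator
therefore emulates the *statistical structure* of that study, and all
pipeline-level results in this repository are statements about data of
that structure, not about the original spectra.

**Concentrations.** Each sample draws (PSC, WSE, ASE, SFT) in mg/g from
its region's published mean/SD, clipped to the published min/max
(default `truncated-normal`; clipping rather than rejection keeps the
mean close to the published one). A moment-matched `lognormal` option
reproduces the pronounced right skew of the published ranges (e.g. PSC
max ≫ mean) at the cost of a slightly shifted mean. Constituents are
correlated (extracts with polysaccharides +0.5; SFT with PSC −0.3),
reflecting the reported covariation of extracts and the inverse
triterpene/polysaccharide relation. The five individual acids are fixed
proportions of SFT (0.12/0.048/0.104/0.144/0.584, chosen so the
regional acid means sum to the regional SFT mean), keeping the sample
table schema-complete.

**Spectra.** A spectrum over 4,000–12,000 cm⁻¹ (8 cm⁻¹ step) is the
Beer–Lambert mixture Σₖ cₖ·profileₖ of four pure-component profiles,
each a non-negative sum of Gaussian bands at the five characteristic
positions (8256, 6880, 5610, 5180, 4800 cm⁻¹); loadings are scaled so
the combination band near 5180 cm⁻¹ dominates the mean spectrum. On top
sit (in order) a normal baseline offset (SD 0.005), a per-sample region
background signature, multiplicative scatter (1 + slope, slope SD
0.01), an additive offset (SD 0.005) and white noise (SD 0.005 per
channel).

**Region signature.** Concentration distributions alone cannot support
the region discrimination the study demonstrates: the published
regional distributions overlap so heavily that a classifier fed only
concentration-driven spectra plateaus near 70 % accuracy, while the
study reports 92.59 % on real spectra. Real provenance information
plausibly lives in matrix absorption and physical-texture differences
beyond the four modelled constituents, so the generator encodes it
explicitly: five broad background bands (centres 10400–4450 cm⁻¹) with
region-specific weights, per-sample weight jitter (SD 0.15) and
amplitude 0.03. Amplitude and jitter were calibrated once so that
held-out random-forest accuracy lands in the low-90s percent — the
published envelope — and then frozen. The component loadings and
scatter/noise levels were likewise calibrated once so the quantitative
pipeline attains the published precision class (R² > 0.95, RE ≈ 3–4 %).
These are declared fictions: they match the published peak positions,
moments and attainable performance, not any measured pure-component
spectrum.

**Not emulated:** instrument line shape and detector response, water
vapour/temperature effects, wavelength-dependent (tilted) scatter,
inter-batch drift, and any real covariance between constituent spectra.
Passing tests therefore show the *pipeline* is correct and well
calibrated under the assumed structure; they do not re-validate the
original instrument results.

## Pretreatment operators

- **SNV** centres and scales each spectrum using the sample (n−1)
  standard deviation — stated explicitly because either convention
  changes values.
- **MSC** regresses each spectrum on a reference by OLS and inverts the
  fitted affine distortion. The reference is the column-wise mean of the
  data MSC is *fitted* on; `apply_pretreatment` returns that state and
  re-applies it unchanged to validation data, so no validation
  information leaks into the correction.
- **Savitzky–Golay** uses an 11-point quadratic window by default (the
  study states no settings; these are common chemometric choices,
  exposed in `PretreatmentSpec`). "Smooth" is SG smoothing (deriv = 0),
  not a moving average, since SG is the smoothing method the field
  names. SG-1D scales by the wavenumber step so units are absorbance
  per cm⁻¹, and refuses a non-uniform axis (relative tolerance 1e−6).
  Edges are handled by the one-sided polynomial fit, preserving shape.
- Composed names smooth first, then scatter-correct.

## Outlier screening (MCCV)

500 rounds; each draws a random 80 % calibration subset, fits an inner
5-factor PLS1 model and records absolute held-out residuals. A sample is
flagged when its residual mean (or SD) exceeds the across-sample mean
plus 3 across-sample SDs of that statistic. Screening runs per quality
parameter; a sample flagged for any parameter is excluded globally.
All parameters are configurable; none can be pinned down from the
published outcome (3 of 138 excluded). Note that with the published
right-skewed concentration distributions, a few genuinely extreme but
valid samples (~2 % per response) exceed the 3σ thresholds on clean
data — the screen trades a small false-flag rate for reliable recovery
of gross artifacts, which simulations show are flagged at 10× band
amplitude with the thresholds untouched.

## Kennard–Stone splitting

Classical unsupervised K-S on the spectra (Euclidean distance, raw by
default): the most distant pair seeds the calibration set and each
subsequent member maximises its minimum distance to the selected set;
ties resolve to the lowest sample index, making the split fully
deterministic. Calibration size is round(n·r/(r+1)); 135 samples at 4:1
give 108/27.

## PLSR

Single-response NIPALS (PLS1), one model per quality parameter; X and y
are mean-centred, not autoscaled (absorbance columns share units). The
factor count is chosen by 10-fold CV (seeded shuffle, pooled held-out
residuals): the smallest count whose RMSECV is within 2 % of the global
minimum — a parsimony margin; 0 recovers the strict argmin. During CV
the per-fold NIPALS decomposition is computed once at the maximum
factor count and truncated, so candidate counts share folds exactly.
Rank exhaustion inside a fold truncates the candidate range; in a
direct fit it is an error.

R² for each set uses that set's own measured mean (the published
formula reuses one symbol for both; per-set means are the default,
switchable in principle to the calibration mean). RE is the mean of
per-sample absolute relative errors over the validation set, undefined
(an error) when a validation value is zero.

The grid search fits every named pretreatment (state learned on
calibration spectra only), selects factors per method, and picks the
method with minimal RMSEP (ties: higher R²pre, then first listed).

## Region classification

Random forest: 500 bootstrap-resampled Gini trees, √p features per
split, unlimited depth, minimum leaf 1 (canonical settings; the study
states none). Tree growth is delegated to scikit-learn; predictions are
the majority vote with ties resolved by the fixed class order
YN < XQ < DBM. Input is SNV-pretreated spectra by default (the study
does not state the classifier's pretreatment). Out-of-bag error is
available as a sanity check and tracks held-out error within a few
points at the default dataset size.

## Reference chemistry

Extract content is (W₁ − W₀) × f / S × 100 % with the aliquot factor f
generalised from the fixed 2 (25 of 50 mL) so the ethanol variant
reuses the operation. Standard curves are OLS lines (r² = squared
Pearson correlation; residual SD with n−2 denominator). LOD/LOQ follow
the ICH convention 3.3σ/S and 10σ/S — the published table prints values
without formulas, so the convention is declared rather than inferred,
and published LOD/LOQ values are not used as check targets. Region
summaries display at 2 decimals; internal precision is full.

## Pipeline and reproducibility

Stages run in the study's order: outlier screen → K-S split →
pretreatment grid per parameter → classification on the shared split.
One global seed fans out to per-stage seeds by fixed offsets (+101
MCCV, +202 CV folds, +303 forest), so disabling a stage does not shift
another's random stream; identical config + seed gives metric-identical
manifests. The default problem size throughout (tests, analysis
scripts, acceptance script) is the full 138 × 1001 study geometry; the
test suite uses a reduced 28-sample, 201-channel configuration where a
full-size run adds nothing to the property under test.

## Known limitations

- The generator's loadings and region signature are calibrated fictions;
  conclusions transfer to real spectra only insofar as the assumed
  structure holds.
- MCCV thresholds assume roughly unimodal residual statistics; heavily
  contaminated data (many simultaneous outliers in a small set) can
  mask one another.
- The multiplicative-scatter advantage of SNV/MSC over raw spectra
  emerges clearly only when calibration samples are few or scatter is
  strong; with generous calibration data, PLSR absorbs mean-direction
  scatter on its own.
- No wavelength selection, no PLS2, no probability calibration, and no
  instrument I/O beyond delimited text and single-spectrum JCAMP-DX.
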