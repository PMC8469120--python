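# Methods

This note documents the models and procedures implemented in phenocanopy,
the conventions that were genuinely open choices, and what the synthetic
fixtures do and do not establish about real images.

## Segmentation model

Vegetation against a dark, non-reflective floor is separated by channel
imbalance rather than absolute brightness. For each pot ROI (everything
outside the ROI is first set to black, which also makes the result provably
independent of neighboring pots):

1. **Channel differences.** `G ⊖ R` and `B ⊖ G`, where `⊖` is saturating
   8-bit subtraction (negative values clamp to 0). Saturation is the
   behavior of an 8-bit image calculator and is deliberate: a pixel with
   more red than green is non-plant by construction, and clamping removes
   its sign information before thresholding. The second difference, B − G,
   is retained as a complementary mask for leaves the first one misses;
   because healthy leaves have G > B it fires rarely, and users who want a
   different second band can swap it via `SegmentationParams`.
2. **Despeckle ("Remove Outliers").** A rank filter with a circular
   neighborhood (pixels whose centers lie within Euclidean distance
   `radius`, center included, truncated at image edges). A pixel `v` is
   replaced by the neighborhood median `m` when `v − m > threshold` (bright
   polarity; `m − v` for dark). All medians are computed from the input
   image, so replacements never cascade. Defaults: radius 10 px,
   threshold 50, bright.
3. **Band thresholds**, inclusive on both ends (standard threshold-tool
   semantics): (30, 255) on G ⊖ R and (3, 255) on B ⊖ G, fixed because the
   chamber illumination is constant.
4. **OR fusion** of the two binary masks.

*Filter-before-threshold.* The despeckle step runs on the grayscale
difference, before thresholding. Its deviation threshold of 50 is an
intensity, which is meaningless on a binary image; filtering first is the
only order in which the documented parameters are coherent.

*Median convention.* Neighborhood sizes vary at image edges and can be even.
The filter uses the lower median — sort ascending, take index
`⌊(n − 1)/2⌋` — which is integer-valued, deterministic, and exactly
reproducible by a brute-force oracle. The implementation routes interior
pixels through a C rank filter and recomputes the edge band exactly with
in-bounds gathers, since library padding modes cannot express edge
truncation.

*Coordinates.* Pixels are 0-based with centers at integer coordinates;
rectangles are half-open `[x0, x1) × [y0, y1)`; circles use center distance
≤ r. The same containment rule drives ROI zeroing and thermal zonal
statistics, so pixel bookkeeping is identical across modules.

## Pixel classifier

The split of masked pixels into green and yellow leaves uses per-class
probability densities with maximum-posterior assignment. The density family
is a full-covariance multivariate Gaussian on raw RGB — the simplest
closed-form choice for unimodal leaf-color clouds: class mean = sample mean,
class covariance = n−1 sample covariance plus `ε·I` (ε default 1.0, which
keeps the model well-defined for nearly monochrome training sets), priors =
empirical class frequencies with an `equal_priors` option since either
convention is defensible. At least 4 training pixels per class are required.
Exact posterior ties go to green (label 1), a documented deterministic
tie-break. Soil suppression is left to the masks: the classifier
deliberately has no third class, and a K-means-style unsupervised split is
not offered because unsupervised color clusters are unstable on senescing
canopies.

The estimator follows the scikit-learn protocol (`fit`, `predict`,
`predict_log_proba`, `get_params`), so it can sit in sklearn pipelines;
models persist as JSON (means, covariances, priors, epsilon).

Digital biomass is the label-1 pixel count. Area conversion divides by the
square of the px/mm scale from a ruler calibration (e.g. a 300 mm ruler
spanning 3000 px gives 10 px/mm); multi-view protocols (one top + four side
views on a turntable) sum the per-view areas.

## Thermal module

Raw 16-bit values are interpreted as centikelvin: °C = raw/100 − 273.15.
This is the unique affine law consistent with the two reference pairs
(29,200 → 18.85 °C; 29,350 → 20.35 °C) and the native encoding of the class
of sensors involved; values outside [20,000, 40,000] trigger a plausibility
warning. No radiometric or emissivity correction is applied. Pseudocolor
rendering uses `n_bins` equal-width half-open bins over
[low_raw, high_raw] (defaults 29,200–29,350, 8 bins — the bin count of the
visual rendering is a free display choice), clamped so out-of-range values
fall in the end bins. Zonal statistics include pixels whose centers fall in
the geometry (the common zonal-statistics default), exclude nodata, and
report mean/min/max/count in °C.

## Growth and treatment statistics

* **Pearson correlation** with a two-sided t-test on n − 2 df. Digital vs
  conventional biomass can be pooled across growth stages (headline
  correlation) or computed per stage; both are exposed, because stage-wise
  correlations answer a different question (within-stage resolution) than
  pooled ones (overall proxy quality).
* **ANOVA + Tukey HSD**: one-way F test plus all pairwise comparisons with
  studentized-range adjusted p-values at a configurable α (default 0.05).
  Identical-constant groups are rejected as degenerate rather than returning
  NaNs. With two groups Tukey reduces exactly to the pooled two-sample
  t-test, which the tests verify.
* **Per-day linear model**: OLS with treatment dummies against a reference
  level; the intercept is the reference mean and each coefficient's
  two-sided t-test p-value corresponds to the `Pr(>|t|)` column of an R
  `lm` summary. This and Tukey are both available because published
  treatment tables come from either contrast style.
* **Germination**: visual emergence calls are operationalized as the first
  sampling day with green area ≥ `min_area_px` (default 50 px — roughly a
  5 mm × 1 mm cotyledon pair at 10 px/mm; configurable because it is an
  explicit operationalization, not a measured constant). Cumulative
  germinated fractions per treatment are nondecreasing by construction.
* **Growth summaries**: per (treatment, day) mean green pixels with
  SE = sd/√n (ddof = 1); a single replicate yields SE = NaN rather than 0.
  Missing sampling days stay missing — no interpolation, since thrice-weekly
  sampling leaves gaps that interpolation would disguise as data.

## Synthetic fixtures: what they emulate, and what they don't

`fixtures` renders top-view scenes (dark floor, rosettes of elliptical
leaves, optional soil discs), thermal rasters (flat base + per-ROI offsets +
rounded Gaussian noise) and growth cohorts (per-pot logistic green-area
curves with treatment multipliers, optional drought-window depression
emulating stress and recovery, programmed emergence days, multiplicative
noise; conventional weights as an affine function of pixels plus Gaussian
error). Everything is deterministic given the spec and seed.

Two deliberate constructions make zero-tolerance tests meaningful:

* **Margin guarantee.** Rendered leaf pixels always have G − R in [40, 50]:
  at least 10 units above the 30 threshold, and at most the despeckle
  deviation threshold of 50, so the filter provably never alters a plant or
  background pixel. Background and soil use luminance-only noise (one
  offset added to all three channels), making their channel differences
  exactly zero. Under these margins the fused mask equals the rendered
  plant mask pixel for pixel.
* **Correlation calibration.** For a target pooled correlation r, the
  weight-noise standard deviation is set from the closed-form attenuation
  `r = 1/√(1 + σ²/var(a·signal))`, so the generated tables carry a known
  true correlation.

Soil discs use a brown (90, 70, 50) whose channel differences saturate to
zero, so they are excluded by the masks. That is the realistic behavior of
the two-band rule for dull brown soil; the occasional soil leak seen in real
images comes from highlights and mixed pixels that these fixtures do not
render. Consequently the zero-error pipeline tests certify the *algorithmic
chain* (masking, filtering, classification, counting), not robustness to
real-world nuisances: specular highlights, leaf overlap (which biases
projected area low), shadows, mixed boundary pixels, illumination drift.
Claims about those require real images.

Default cohort conditions mirror a four-arm wheat-style design — control,
drought at stem elongation (days 38–44, depression 0.6), drought at heading
(days 45–51, depression 0.5), high nitrogen (growth multiplier 1.15), four
replicates, sampled every second day from day 7 to 57, logistic carrying
capacity 60,000 px — and a sugar-beet-style germination schedule is
expressed through per-treatment emergence-day lists. Depression factors and
the noise level (5% multiplicative) are single fixed choices of plausible
magnitudes for visible stress effects, not fitted values.

## Numerical and degenerate-input choices

* Threshold bands are inclusive on both ends; `low > high` is rejected.
* An ROI wholly outside the image raises an error naming it, as does a zonal
  ROI with zero valid pixels.
* Correlation requires n ≥ 3 and nonzero variance; ANOVA requires ≥ 2 groups
  of n ≥ 2 and nonzero within-group variance; the dummy-coded lm rejects
  singular designs.
* Label images may contain only {0, 1, 2}; anything else is an error, not a
  silent drop.
* Biomass CSV columns are fixed (`pot_id, day, green_pixels, yellow_pixels,
  total_pixels`) and data files carry no timestamps, so pipeline re-runs are
  byte-identical.

## Problem sizes used in the test suite

Scenes are 60×120 to 120×120 px with radius-10 filtering; filter-vs-oracle
equivalence uses 50 random 15×15 images plus exhaustive small cases; the
classifier check uses 10,000 simulated pixels; the ANOVA calibration uses
2,000 null simulations; zonal oracles run on 50×50 rasters. These sizes make
every check exact or tightly bounded while keeping the suite fast; the
algorithms themselves are size-independent, and the segmentation filter
processes large frames in a single pass per band.

## Known limitations

* No automatic pot detection; ROIs come from the layout file.
* No multispectral band alignment, emissivity/atmosphere correction, or
  radiometric calibration of the thermal sensor.
* Projected area underestimates biomass once leaves overlap heavily; the
  correlation machinery quantifies, but cannot remove, that bias.
* The Gaussian color model assumes unimodal class colors; heavily variegated
  leaves would need a mixture model.
* No mixed-effects/longitudinal modelling; statistics are the classical
  per-day and pooled analyses described above.
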