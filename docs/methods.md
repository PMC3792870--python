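# Methods

`splitscore` implements an end-to-end analysis for multiplex sandwich
antibody arrays used in serum biomarker discovery: spot-level preprocessing,
a split-point score panel classifier, diagnostic evaluation, a per-marker
differential screen, and a synthetic spot-level cohort generator used for
validation. This note records the model, the conventions the data alone do
not determine, and what the synthetic validation does and does not show.

## Preprocessing model

A slide carries several sub-arrays (incubation chambers); each sub-array is
incubated with one serum sample and carries duplicate capture-antibody spots
per analyte plus positive-control spots. The preprocessing chain is:

1. **Replicate aggregation.** Cell value = mean over the two replicate spots
   of `max(fg_median − bg_median, 0)`. Negative background-subtracted
   intensities are clamped to zero before averaging: fluorescence signal
   cannot be negative, and clamping before the mean keeps the estimate of a
   near-zero signal non-negative.
2. **Positive-control normalization.** Each sub-array is multiplied by
   `reference / (its positive-control mean)`. The default reference is the
   grand mean of all sub-arrays' positive-control means, which removes
   relative slide/sub-array scale differences while preserving the overall
   intensity scale; any fixed reference (e.g. a known control concentration's
   nominal level) may be supplied instead.
3. **Detection threshold.** Buffer-only blank sub-arrays give a
   limit-of-detection model: `cutoff = mean + k·SD` of the per-blank
   aggregate signals, `k = 2` by default, with the sample (n−1) SD since the
   number of blanks is small (10 by convention). Only the upper bound is
   used: the threshold answers "is this signal distinguishable from
   background?", a one-sided question. Blank sub-arrays contain no positive
   controls of their own (every spot is a buffer blank), so each blank is
   rescaled by its slide's mean positive-control level, estimated from the
   serum sub-arrays sharing the slide; this puts the cutoff on the same
   scale as the normalized marker values and removes pure slide-scale
   effects from the blanks exactly when replicate noise is absent.
4. **Flooring and filtering.** Values below the cutoff become the floor
   value 1 (non-detection); a value exactly at the cutoff is kept as signal
   (configurable). Markers floored in every sample are removed.

If a sample was assayed on several sub-arrays its normalized values are
averaged before flooring (flooring an average is better-behaved than
averaging floored values). Extra single-analyte columns from the sample
sheet (e.g. a CA125 ELISA concentration, IU/ml) join the matrix after these
steps, bypassing normalization and flooring: they are not array
measurements, and split-point scoring is scale-free per marker, so mixing
scales across columns is harmless.

## Split-point score classifier

For one marker with values `x_i` and binary labels, a split point `s`
partitions the axis into a control interval and a cancer interval
(orientation either cancer-above or cancer-below). The fitted split
minimizes the number of misclassified training samples. Because the error
is piecewise constant in `s`, it suffices to evaluate midpoints between
adjacent distinct sorted values plus one sentinel below the minimum and one
above the maximum; midpoints also maximize the separation margin within
each optimal interval.

Deterministic conventions (the data do not pin these down):

* a value exactly at the split falls in the **control** interval;
* ties on training error are broken by larger margin (gap between the
  adjacent training values around the split), then smaller split value,
  then orientation cancer-above. Note that the margin is a property of the
  value scale, not of the ordering: under a nonlinear strictly increasing
  transform the *error* of the fitted rule is always preserved, but when
  several intervals tie, the max-margin tie-break may select a different,
  equally good interval, so individual votes are guaranteed
  transform-invariant only when the minimizer is unique;
* a panel of N rules scores a sample as the number of markers voting
  cancer (an integer in [0, N]); the decision is cancer iff the score
  reaches the threshold T (`score ≥ T`; a score exactly at T is cancer).
  T is fitted by minimizing training misclassification over T ∈ [0, N+1],
  ties to the smallest T, or pinned by the user at a chosen operating
  point (the classical choice for a 5-marker panel is T = 3);
* marker ranking (panel selection) sorts by per-marker training error,
  ties by larger margin then lexical marker id. This replaces opaque
  model-based predictor selection with a deterministic filter that uses
  the same objective as the classifier itself.

## Evaluation

Confusion metrics use cancer as the positive class; sensitivity,
specificity, PPV, NPV and accuracy are reported as exact proportions and as
percentages rounded to one decimal. A rate with a zero denominator is
reported as NaN with an explicit flag, never silently as 0. The ROC sweeps
`score ≥ threshold` over all distinct score values (so a 5-marker panel has
at most 7 operating points), includes the all-negative and all-positive
endpoints, and integrates by the trapezoidal rule — equivalent to the
Mann–Whitney statistic with ties counted ½. Pearson correlation (with the
t-transform p-value) serves as the slide-reproducibility QC statistic.

## Differential screen

Per marker, a two-sample t-test on log2 intensities (variance stabilization
for multiplicative fluorescence data; floored values of 1 map to 0),
Welch's unequal-variance variant by default, with Benjamini–Hochberg
adjustment across markers. Student's variant and Bonferroni/no adjustment
are available; the choice is recorded in the result table's metadata.
Group means are reported on the raw intensity scale for interpretability.
A marker with zero variance in both groups gets p = 1 when the group means
agree and p = 0 when they differ deterministically.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 34 cancer /
53 control serum samples, 174 markers in duplicate, positive-control spots
per sub-array, 10 buffer blanks, 8 sub-arrays per slide, a multiplicative
per-slide scale effect, and ~10% replicate CV (typical for the platform).
Log-scale intensity model per sample `i`, marker `m`:

    log V[i,m] = mu_m + delta_m · 1[i is cancer] + eps[i,m]

* `mu_m`: per-marker baseline, uniform within ±0.8 around log(500)
  fluorescence units. Baselines are drawn from a separate
  `population_seed` (fixed default), because they are population biology:
  two cohorts generated with different cohort seeds are then independent
  samples from the *same* population, which is what held-out evaluation
  presupposes.
* `eps`: within-group deviation, SD 0.35 on the log scale.
* Spiked ("panel") markers carry `delta_m = ±3.0` within-group SDs
  (direction per marker; the default panel spikes five markers, three up
  and two down). For spiked markers, `eps` is drawn from a truncated
  Gaussian with support ±1.25 SD in *both* groups, so a 3-SD shift yields
  genuinely disjoint class intervals separated by a 0.5-SD gap. This
  bounded-support choice encodes the structure the split-point model
  assumes — that a class boundary exists per marker — and makes "zero
  training error, fitted split inside the gap" a well-defined recovery
  target. Non-spiked markers remain ordinary Gaussians, so they are a
  clean null for t-test calibration.
* Each spot records `fg = bg + slide_factor · replicate_noise · V` with
  `bg ~ N(50, 5)` clipped at 0, `slide_factor = exp(N(0, 0.2))` shared by
  all spots of a slide (positive controls and blanks included, so
  normalization can undo it), and mean-one log-normal replicate noise at
  the configured CV (exactly 1 when the CV is 0). Blanks sit near 60 units
  (SD 10), far below marker signal; under the defaults well under 1% of
  true marker values fall below the resulting cutoff.
* Blank sub-arrays are interleaved evenly among sample sub-arrays, as on a
  real run, so every slide carrying blanks also carries serum sub-arrays
  whose positive controls pin down its scale factor.
* An optional CA125-like ELISA column (log-normal, IU/ml scale, ~1.6-SD
  group shift) can be added to the sample sheet to exercise the
  extra-analyte path.
* One RNG stream per cohort (NumPy PCG64 via `default_rng(seed)`), fixed
  draw order: output is bit-identical for a fixed seed. Replicate-slide
  generation derives one sub-stream per slide set from the cohort seed and
  adds per-(sample, marker) log-normal discordance of configurable SD;
  concordance is monotone decreasing in that SD and exactly 1 when both it
  and the replicate CV are 0.

**What passing the synthetic checks shows — and does not.** The generator
produces clean log-normal intensities with exactly the assumed structure
(multiplicative slide effects fully explained by positive controls,
independent replicate noise, disjoint class intervals for spiked markers).
Real serum arrays add spatial artifacts, scanner saturation, antibody
cross-reactivity, heavy-tailed biological variation and overlapping class
distributions, none of which are emulated. Recovery results on synthetic
cohorts therefore validate the *implementation* (the pipeline finds
structure that is truly there, with calibrated error rates), not the
clinical performance of any particular marker panel.

The `worked_example_fixture` is a deterministic 87-sample, 5-marker matrix
built so that at T = 3 the confusion counts are tp=34, fn=0, tn=50, fp=3:
overall agreement 84/87 = 96.6%, sensitivity 100%, specificity
50/53 = 94.3%. (Note 50/53 rounds to 94.3%, not 95%: no integer count of
53 controls is consistent with both 95% specificity and 96.6% overall
agreement over 87 samples; the package reports exact proportions.)

## Problem sizes and numerical choices

* Parameter recovery runs at n = 200/group with the default 174 markers —
  large enough that ranking separates spiked from null markers by a wide
  margin (null decision stumps misclassify ≳40% of 400 samples; spiked
  ones ~0).
* Null calibration pools 20 independent cohorts of 500 null markers at
  n = 15/group (10,000 marker-tests), giving a Monte-Carlo SE of ~0.002 on
  the rejection fraction against the ±0.01 acceptance band.
* The oracle check compares the fitted split against exhaustive enumeration
  on 1000 random instances of up to 12 samples, half of them with heavily
  tied integer values.
* Floating-point: normalization equality is asserted to 1e-9 relative;
  AUC invariance to 1e-12 absolute; all counts are exact integers.

## Known limitations

* Split-point fitting is univariate; the panel ignores marker
  correlations, and the unweighted vote cannot express relative marker
  quality beyond inclusion.
* Training-error-based ranking and threshold fitting are optimistically
  biased on the training cohort; honest performance estimates require an
  independent cohort (as in the examples) or resampling, which the package
  leaves to the user beyond the seeded stratified splitting hooks.
* The blank-based cutoff assumes blanks share the slides' noise regime; a
  cutoff from blanks on unrepresentative slides will mis-floor values.
* Two-color arrays, vendor binary formats, spatial/batch correction beyond
  positive-control scaling, and quantile/log-ratio normalization are out
  of scope.
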