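# Methods

`kiwifusion` re-creates, end to end, a nondestructive kiwifruit ripening
study that pairs a 13-channel metal-oxide-semiconductor (MOS) electronic
nose with proximal Vis/NIR hyperspectral imaging, and asks whether
feature-level fusion of the two sensing modes improves storage-day
classification and the prediction of firmness, soluble solids content
(SSC) and titratable acidity (TA).  Because no public dataset of this kind
exists, the package ships a synthetic-experiment generator that is a
first-class, tested component: its defaults *are* the study conditions, and
every downstream stage (feature engineering, wavelength selection,
modeling, evaluation) is exercised against it.

## The synthetic storage experiment

**Design.** Eight sampling days (0, 2, 5, 8, 11, 14, 17, 20) x 15 fruits
per day = 120 fruits, mirroring the classic completely randomized
postharvest design.

**Quality attributes.** Each attribute follows a logistic day-mean
trajectory (ripening accelerates, then plateaus after ~day 14) plus an
independent Gaussian within-day residual:

| attribute | start | end  | midpoint (d) | rate (1/d) | residual SD |
|-----------|-------|------|--------------|------------|-------------|
| firmness  | 7.8 N | 2.6 N| 6            | 0.5        | 0.206 N     |
| SSC       | 7.0 %Brix | 11.44 %Brix | 6 | 0.5       | 0.299 %Brix |
| TA        | 1.30 %| 0.82 %| 6           | 0.5        | 0.0164 %    |

The ranges are solved in closed form from
`SS_between = n_per_day * delta^2 * sum_d (g_d - g_bar)^2`
(logistic shape sum 1.1525 over the default days) so that a one-way ANOVA
on a default experiment reproduces the reference between-day sums of
squares (~471, ~341, ~4.0) and error mean squares (0.042, 0.089, 0.00027);
the residual SDs are the square roots of those error mean squares.  Values
accidentally driven non-positive are clipped to a small floor and logged,
never silently rejected (rejection would bias the day means).

**E-nose recordings.** The acquisition protocol is 210 s cleaning / 40 s
headspace exposure / 60 s purge at 1 sample/s (311 samples).  Each fruit
carries one latent aroma intensity: the common logistic ripening progress
of its storage day plus fruit-level aroma noise (SD 0.03).  The nose senses
the fruit's overall ripening state, not the individual attribute residuals
— this is the key realism assumption that makes the two sensing modes
complementary rather than redundant.  Channels rise first-order (tau 8 s)
toward `baseline * (1 + gain * intensity)` during exposure and decay
exponentially (tau 15 s) during purging, with Gaussian sensor noise (SD
0.02 raw units).  The hydrocarbon-sensitive TGS822, TGS2610 and MQ9 carry
the largest aroma gains, so their MSR/AUC features dominate — matching the
loading structure reported for real kiwifruit.

**Reflectance spectra.** 568 bands over 400-950 nm with the half-open-grid
convention `lambda_i = 400 + i * 550/568`; trimming to the 450-900 nm
working range then retains exactly 465 bands (an endpoint-inclusive grid
would retain 464 — the convention is deliberate and load-bearing).  A
sigmoidal continuum carries ten planted Gaussian features (sigma 5 nm),
each linear in exactly one driver:

* three firmness bands (480/640/820 nm, gain 0.040 per N),
* three SSC bands (530/700/880 nm, gain 0.028 per %Brix),
* two TA bands (580/760 nm, gain 0.60 per %),
* two storage-day bands (660/740 nm, gain 0.004 per day) emulating
  chlorophyll-style optical aging that keeps progressing after the quality
  attributes have plateaued — without it, no optical sensor could separate
  days 14/17/20, and the eight-class duty would be impossible for the
  spectral and fused modes alike.

Two spectral noise sources play different roles.  Independent per-band
read noise (SD 0.005 reflectance) can be defeated by pooling bands; a
per-fruit *optical mismatch* (SD 0.5 N / 0.45 %Brix / 0.045 % / 0.75 day,
shared by all bands of a driver) cannot, and therefore sets the floor of
spectra-only prediction error.  The mismatch SDs are calibrated to the
reference single-modality validation errors (SG1D-PLSR: 0.539 N, 0.501
%Brix, 0.049 %).  This split matters twice: it reproduces the realistic
regime in which each sensing mode is individually imperfect (so fusion
genuinely helps, the study's central claim), and it keeps per-band SNR
high enough that CARS coefficient ranking is meaningful.

**What the generator does not emulate** (and hence what passing tests do
not show about real fruit): no VOC chemistry — aroma is a single latent
scalar, which caps e-nose class structure at one dimension and is the main
reason PLSDA accuracies here (20-40%) sit far below published values
(~85%) while the polynomial SVM (64-86%) behaves reasonably; no MOS
humidity/temperature drift; no scattering artifacts, so SNV/MWS have
nothing real to correct (they are exercised as contracts, not as
improvements); Gaussian noise everywhere; attribute-band couplings exactly
linear.

## Feature engineering

E-nose: fractional baseline correction `y = (x - x0)/x0` with `x0` the
mean raw response over 200-210 s (the estimator is undefined in the
protocol description; the last 10 s of cleaning is the declared choice),
then per channel over the inclusive 211-250 s headspace window: MSR (max),
AUC (trapezoidal integral, dimensionless-seconds), Tim (seconds from
window start to the *first* sample attaining the maximum) — 39 features,
sensor-major.

Spectra: dark/white calibration `(raw - dark)/(white - dark)` with an
explicit zero-denominator guard; ROI spectra as the mean over four
randomly placed, non-overlapping (declared interpretation of "different
regions") 5x5 pixel blocks inside the fruit mask, seeded; band trimming;
three alternative pretreatments applied independently to the trimmed
spectra — moving-window mean (window 5, shrinking at the edges), first
Savitzky-Golay derivative (window 5, quadratic, reported per band step,
one-sided polynomial fit at the edges), and SNV (row-wise centering to
unit sample SD, n-1 divisor).

## CARS wavelength selection

100 Monte-Carlo sampling runs.  Per run: fit PLS1 on a random 80% of
samples over the surviving wavelengths, with the component count chosen by
inner 10-fold CV (up to 20); rank by |regression coefficient| (ties break
toward the lower wavelength index); enforce the exponential-decay-function
retention count `r_i = a e^{-k i}` fixed by `r_1 = 1`, `r_N = 2/p`; then
adaptive reweighted sampling — p draws with replacement proportional to
|coefficient|, distinct outcomes survive.  Drawing p (not `r_i * p`) times
is essential: otherwise the distinct-survivor collapse (~0.63x per run)
compounds and retention crashes within ten runs instead of following the
documented sharp-then-shallow schedule.

Each run's survivor set is scored by 10-fold RMSECV of a PLS model using
one fold split and one component count fixed for the whole trajectory (the
count is chosen once on the full spectrum by CV).  Scoring every subset on
the same folds and model order makes the RMSECV curve a comparison of
subsets; re-randomizing either per run lets large early subsets win by
fold luck.  The selected set is the survivor set of the run minimizing
RMSECV (earliest on ties).  For the classification duty CARS regresses on
the integer storage-day labels.  On default synthetic data the best run
lands at median ~55 of 100 and selects 8-72 of 465 bands.

## Models

All estimators are scikit-learn compatible (`fit`/`predict`,
`get_params`, trailing-underscore fitted attributes) and are fit on
feature tables z-scored with calibration-row statistics only.

* **PLSR** (`CVPLSRegressor`): component count by minimum 10-fold RMSECV
  (cap 20); numerical near-ties (<= 1e-9 x response SD) resolve toward
  fewer components so the noiseless fixture recovers the true dimension.
* **PLSDA** (`PLSDAClassifier`): one-hot dummy block, argmax decoding, LV
  by minimum CV RMSE on the dummy block.
* **SVR/SVM** (`GridPolySVR`/`GridPolySVC`): polynomial kernel
  `(gamma <x, x'> + 1)^2`, exhaustive 5x5 grid over c and gamma in
  {0.01, 0.1, 1, 10, 100}, selected by smallest 10-fold validation RMSE.
  For classifiers the RMSE is computed on one-hot class-coded predictions
  (so a misclassification rate m maps to RMSE `sqrt(2m/K)`), which is the
  scale on which reference classifier RMSEVs (~0.11) are reported.  SVR
  standardizes the response internally with epsilon = 0.01 SD units —
  without this the default epsilon tube would swallow the whole TA range.
  libsvm is capped at 200k iterations; a few ill-conditioned grid corners
  otherwise never terminate, and they never win the search.

**Fusion** concatenates the 39 e-nose features with the CARS-selected SG1D
wavelengths (e-nose block first), then z-scores on calibration rows.  SG1D
is the fused spectral basis because it is the best-performing pretreatment
for these duties; per-duty CARS selections are computed independently on
the calibration rows only (no test leakage).

## Evaluation

70/30 calibration/test split, stratified by storage day via
largest-remainder apportionment (120 -> 84/36; per-day counts deviate from
proportionality by at most one).  Regression: R^2 and RMSE from their
definitions.  Classification: overall accuracy = trace/total of the
confusion matrix, with per-class tp/fp/fn/tn by one-vs-rest reduction.
One-way ANOVA with p from the F distribution, cross-checked against
`scipy.stats.f_oneway`; Tukey HSD letters by insert-and-absorb over the
`statsmodels` pairwise decisions.  Validation metrics are 10-fold
cross-validation predictions on the calibration rows at the already-chosen
hyperparameters.

## Problem sizes and reproducibility

The default study (120 fruits, 4 duties x 3 modes x 2 model families,
100-run CARS per duty) completes in about a minute on one core; the
multi-seed property studies in the test suite use ten seeds of exactly
this default study.  All randomness flows through
`numpy.random.SeedSequence` children of a single seed; fixed seeds give
bit-identical serialized bundles and identical reports (timings aside).
The pipeline config is a validated JSON document (`kiwifusion schema`
prints its JSON schema) and its hash is recorded in every report.

## Known limitations

* The one-dimensional aroma latent caps e-nose classification; PLSDA in
  particular degrades to 20-40% eight-class accuracy (see above).
* ENVI support covers band-sequential float32 with the header fields this
  package writes — it is an interchange convenience, not a general reader.
* CARS run counts and selected-set sizes are order-of-magnitude
  reproductions; the reference instrument's exact grid and the authors'
  internal CARS settings are not published, so printed per-duty selection
  counts (34-72) are context, not targets.
* Tukey letter displays use the common insert-absorb heuristic, which is
  standard but not guaranteed minimal in the number of letters.
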