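# Methods

## Scope and model

`bodyrad` analyses one axial CT slice per patient at the L3 level. The
analysis chain is: tissue segmentation by HU windows inside anatomical
compartments → body-composition indices → 2D radiomics on a 2 mm grid →
80:20 train/holdout split (stratified by site) → per-feature Yeo-Johnson
standardization fitted on training data only → bootstrap stability
selection of radiomics features with cross-validated LASSO Cox → signature
pooling by backwards stepwise-AIC Cox → unpenalized Cox score fits →
discrimination and risk-stratification evaluation.

Survival follows a proportional-hazards model throughout: scores are Cox
linear predictors in log-hazard units, and the synthetic cohorts are drawn
from the same model family (Weibull baseline hazard, administrative
censoring), so planted effects are recoverable in principle by the very
estimators the pipeline uses. That alignment is intentional — the phantom
study validates the *machinery*, not the biology.

## Synthetic cohorts

The generator emulates a resected pancreatic-cancer population: age
~ N(67.7, 10.2²) years, BMI ~ N(25.4, 4.2²) kg/m², 53% male, 42% ASA ≥ 3,
sex-specific heights, Weibull baseline with shape 1.2 and scale ≈ 36.84
months (solved so that 45% die by 24 months), administrative censoring at
60 months, optional uniform dropout (off by default).

Phantom slices are concentric ellipses — an outer SAT annulus, a muscle
annulus, and an interior VAT region with an organ and a gas hole excluded
from every compartment. Geometry is deliberately schematic: only HU
distributions, areas and texture statistics feed the downstream analysis.
Body size and SAT thickness grow monotonically with BMI, so fat areas and
BMI correlate as they do in patients. Per-tissue HU fields are Gaussian,
with means placed well inside the segmentation windows (muscle 40 ± 15 HU,
VAT −100 ± 12, SAT −110 ± 12) so ≥ 95% of each tissue's pixels fall in its
window; a single correlation-length knob (Gaussian-filtered white noise,
renormalized to the target SD) controls zone-size texture. Default pixel
spacing is 0.8 mm so the 2 mm radiomics resampling does real work.

Planted effects: `planted_betas` maps feature names — clinical fields,
body-composition indices, or extracted radiomics feature names — to
log-hazard coefficients. Each feature is z-standardized across the
generated cohort before entering the linear predictor, so coefficients read
as log hazard ratios per SD.

What the phantoms do *not* emulate: organ anatomy, contrast phases,
scanner/protocol heterogeneity, segmentation error, informative censoring,
and inter-feature dependence structures of real radiomics panels. Passing
tests therefore demonstrate correctness and calibration of the estimators
under the stated generative model, not clinical validity.

## Numerical and statistical choices

- **HU windows** are closed intervals applied inside the compartment label,
  mirroring the manual-contour workflow. Areas are computed at native
  resolution; resampling to the 2 mm grid happens only for radiomics.
- **Discretization** for texture: fixed 25 HU bins anchored at the ROI
  minimum (configurable). GLSZM zones are 8-connected. The matrix
  identities ΣP = N_z and Σ j·P(·,j) = N_p are asserted on every build.
- **Perimeter** is the iso-0.5 marching-squares contour length of the
  zero-padded binary mask (a single pixel gives 2√2·s, a 2×2 block
  4s + 2√2·s). Known property: on digitized circles this estimator
  converges to ≈ 1.055 × the true circumference (the 8-direction
  corner-cut staircase limit), a bias shared by mesh-based 2D perimeters in
  common radiomics tools; it is a systematic, shape-dependent scale factor,
  not noise.
- **Yeo-Johnson** λ is fitted per feature by bounded Brent search on the
  Gaussian profile log-likelihood over λ ∈ [−5, 5] (tolerance 1e−6),
  followed by centering/scaling to the training mean/SD. Holdout data are
  transformed with the frozen parameters; constant or nearly-empty columns
  are excluded and logged.
- **Bootstrap plan**: B resamples of training size drawn with replacement,
  fixed once and shared between feature selection and signature pooling.
  Resamples with fewer than two events are skipped but still count in the
  cutoff denominator.
- **CV folds inside a bootstrap resample are grouped by source patient**:
  all bootstrap copies of one patient stay in one fold. Without this, the
  fold deviance is evaluated on patients that are simultaneously present in
  the fold's training part, the chosen penalty collapses toward zero, and
  pure-noise features acquire high selection frequencies.
- **Penalty choice**: the LASSO Cox path (coordinate descent on the partial
  likelihood; scikit-survival's coxnet) is scored by the
  Verweij–van Houwelingen cross-validated partial-likelihood difference.
  The default rule takes the strongest penalty within one standard error of
  the deviance optimum (`cv_rule="1se"`; `"min"` available). The 1-SE rule
  keeps per-resample supports sparse enough that selection frequencies
  separate planted from lucky features: with the min rule, single noise
  features reach 50–100% selection frequency on fixed cohorts, defeating
  the purpose of the frequency cutoff; with 1-SE, planted effects of ~1 log
  hazard ratio per SD at n=300 are selected in 83–100% of resamples while
  no noise feature exceeds 7%.
- **Cutoff semantics**: a feature enters the candidate list when its count
  is ≥ cutoff (exclusion is "selected fewer than cutoff times").
- **Stepwise-AIC Cox** starts from the full candidate model and removes the
  single feature whose removal most decreases AIC = 2k − 2·logPL, stopping
  when no removal helps; the empty model is allowed. Fits use an internal
  vectorized Newton–Raphson solver with Efron tie handling (validated
  against lifelines to ~1e−5); monotone likelihoods (a covariate that
  perfectly orders events) are cut off at |β| = 30, where the partial
  likelihood is already at its asymptote. Ties in the modal-signature
  choice break toward the smaller set, then lexicographically.
- **Signature resampling mode**: the default reuses the fixed bootstrap
  plan; `resample_mode="subsample75"` instead draws random 75% subsets
  without replacement, an alternative pooling scheme offered for
  sensitivity analyses.
- **Final scores** are unpenalized Cox fits (lifelines, Efron ties) on the
  full training set; combined scores (CR, CB, CBR) are Cox refits on the
  component linear predictors, preserving each component's internal
  weighting while learning their relative weights. Degenerate components
  (e.g. an empty radiomics signature's constant score) are dropped from
  combinations.
- **Concordance**: a pair is comparable when the earlier observed time has
  an event (tied event times are not orderable and contribute no pair);
  score ties count ½. CIs are percentile patient-bootstrap (B=1000 by
  default, 200 in tests); the p-value tests C = 0.5 via a normal
  approximation over the bootstrap spread. The log-rank p-values reported
  alongside are a different test and are labelled separately.
- **Risk strata** cut at the training score's 25th/75th percentiles;
  boundary ties go to the middle stratum so extreme groups stay ≤ 25%;
  holdout patients use the training cut points unchanged.
- **Z-scores** for body-composition indices use per-sex training-split
  means/SDs only, avoiding holdout leakage; they are descriptive outputs,
  while modelling uses the Yeo-Johnson-standardized features uniformly
  (transforming clinical age/BMI as well, switchable off).

## Problem sizes

Full-scale analyses use B=1000 resamples and a cutoff of 500. The shipped
demo and the validation suite run scaled versions chosen to keep a desk
run short while preserving the statistics being checked: B=100–200 with the
cutoff scaled proportionally (50–100), cohorts of 200–500 patients for
calibration and power checks, 10 repetitions for planted-signature
recovery and 20 for null calibration, and 96×96 phantom grids (the
per-patient slice is 128×128 at 0.8 mm by default). The acceptance script
reports the problem size next to every quantity it computes.

## Known limitations

- The phantom's feature dependence is simpler than real radiomics panels;
  correlation pruning is exercised by construction (duplicated/derived
  features) rather than by realistic redundancy.
- The marching-squares perimeter carries the ≈ +5.5% digitized-circle bias
  noted above.
- Sex-specific radiomics signatures, competing risks, time-varying effects
  and calibration (as opposed to discrimination) are out of scope.
- With small cohorts (n ≲ 150) the 1-SE rule is conservative and the
  radiomics pool is often empty; the pipeline reports this as an explicit
  `empty-pool`/`empty-signature` status rather than an error, and the
  evaluation then shows chance-level discrimination for that score.
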