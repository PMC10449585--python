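# bodyrad

Body-composition **radiomics survival analysis** for single-slice abdominal
CT, aimed at researchers who study how muscle and fat compartments at the
third lumbar vertebra (L3) relate to survival after cancer surgery — and who
want the full statistical pipeline (not just feature extraction) testable
end to end without access to patient data.

The package implements, on synthetic *phantom* cohorts:

1. **Phantom L3 slices** — elliptical-annulus subcutaneous fat (SAT), muscle
   and visceral fat (VAT) compartments with realistic Hounsfield-unit (HU)
   distributions, correlated noise textures, geometry that scales with BMI,
   and right-censored survival drawn from a Weibull proportional-hazards
   model with *planted* log-hazard effects on chosen features.
2. **Conventional body composition** — HU-window segmentation
   (SM −29…150, VAT −150…−50, SAT −190…−30), cross-sectional areas (cm²),
   stature-normalized indices SMI/VATI/SATI (cm²/m²), skeletal-muscle
   radiation attenuation (SM-RA), and sex-specific Z-scores.
3. **2D radiomics** on a fixed 2 mm grid — first-order intensity statistics,
   2D shape (marching-squares perimeter among them), and gray-level
   size-zone matrix (GLSZM) texture features such as SmallAreaEmphasis.
4. **Bootstrap stability selection** — B fixed bootstrap resamples of the
   training set; per resample, Spearman-correlation pruning (|ρ| > 0.90)
   followed by 5-fold cross-validated LASSO Cox; features selected in at
   least a cutoff number of resamples form the *feature pool*.
5. **Signature pooling** — backwards stepwise Cox regression minimizing the
   AIC on the same resamples; the modal feature set becomes the signature.
6. **Named Cox scores** — clinical (C), body-composition (B) and radiomics
   (R) linear predictors `lp = Σ βᵢ·xᵢ`, plus combined CR/CB/CBR refits.
7. **Evaluation** — Harrell's concordance index with bootstrap CIs,
   25/50/25 risk stratification at the training quartiles, Kaplan–Meier
   curves, and log-rank tests, on training and holdout splits.

Published score equations are shipped as frozen defaults, e.g. the clinical
score `0.01353·age + 0.4087·[ASA ≥ 3] + 0.2803·[male]` and the radiomics
score `0.3100·SAT_perimeter − 0.2302·VAT_SmallAreaEmphasis +
0.1353·VAT_Maximum` (on Yeo-Johnson-standardized features); they can be
applied to any feature table via `bodyrad.compute_score`.

## Worked example

```bash
bodyrad run-all --config examples/demo.yaml
```

generates a 304-patient phantom cohort (seed 42) with a planted
visceral-adiposity effect (0.6 per SD of VATI) and a planted radiomics
effect (1.2 per SD of the maximum visceral-fat HU), then runs the whole
pipeline with a scaled-down bootstrap (B=100, pool cutoff 50). On this
machine it prints, from `scratch/demo/evaluation.json` and the stage
artifacts:

```
B: train C=0.603 (0.555-0.639) holdout C=0.649
C: train C=0.564 (0.519-0.606) holdout C=0.553
R: train C=0.736 (0.700-0.767) holdout C=0.695
CBR: train C=0.754 (0.713-0.787) holdout C=0.736

feature pool (top):  VAT_original_firstorder_Maximum  count=57  frequency=0.57
R signature: ['VAT_original_firstorder_Maximum'], coefficient 1.032
```

Reading: the stability selection recovered exactly the planted radiomics
feature (57 of 100 resamples, above the cutoff of 50, no noise feature
selected), the refit R-score discriminates survival (concordance 0.74 on
training, 0.70 on held-out patients; 0.5 would be chance), and combining
clinical, body-composition and radiomics information (CBR) performs best.
Artifacts — cohort CSV, NIfTI slices, feature tables, pools, fitted scores,
Kaplan–Meier step tables, and a manifest of SHA-256 checksums — land in
`scratch/demo/`; rerunning the same config reproduces them bit for bit.

Every stage is also a library call (`bodyrad.generate_cohort`,
`bodyrad.extract_features`, `bodyrad.StabilityFeatureSelector`,
`bodyrad.SignatureCoxModel`, `bodyrad.harrell_c`, …); the estimator classes
follow scikit-learn fit/transform/predict conventions.

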