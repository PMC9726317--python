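# sbtriage

Risk scoring and diagnostic-strategy comparison for potential small-bowel
bleeding (PSBB): bleeding whose source upper endoscopy and colonoscopy
cannot find.

The package implements three connected pieces:

1. **Risk model** (`sbtriage.risk`) — a five-predictor logistic score
   (age, atherosclerosis, chronic kidney disease, antiplatelet use, serum
   albumin) for the probability that the bleeding lesion is *mural-based*
   (arising in the bowel wall, e.g. a small-bowel tumor) rather than
   mucosal (angiodysplasia, ulcer). Mural lesions are better seen on CT
   enterography (CTE); mucosal lesions on video capsule endoscopy (VCE).
   Includes classification at a percent cutoff, confusion metrics, ROC
   curves with trapezoidal AUROC, and Youden-index cutoff selection.
2. **Model derivation** (`sbtriage.derivation`, `sbtriage.fitting`) — the
   full derivation pipeline: seeded cohort split, univariate logistic
   screening with Wald odds ratios/CIs (separating covariates flagged as
   not computable), multivariate fit of the univariately significant
   covariates, final refit on the five prespecified predictors, Youden
   cutoff on derivation scores, hold-out validation. The Newton–Raphson
   logistic fitter detects (quasi-)complete separation.
3. **Decision model** (`sbtriage.cea`) — a deterministic expected-value
   comparison of six diagnostic strategies over a standard 100-patient
   cohort (VCE only, CTE only, model-based triage, VCE→CTE, CTE→VCE,
   triage with crossover), reporting expected missed lesions per lesion
   type, test counts, and cost per patient in USD and THB, plus one-way
   sensitivity analysis over parameter ranges.

`sbtriage.synthetic` generates labelled synthetic cohorts (the original
patient data are not public) for testing the derivation pipeline, and a
patient-level Monte-Carlo simulator that serves as an independent oracle
for the decision model.

## CLI

```sh
# score a cohort CSV with the built-in published formula (cutoff 24.2%)
sbtriage predict --cohort cohort.csv --out scored.csv

# derive a new model from a labelled cohort (70/30 split by default)
sbtriage derive --cohort cohort.csv --seed 1 --fraction 0.7 --out report.json

# evaluate the six strategies at base case (or a JSON/YAML parameter file)
sbtriage cea --out-csv table.csv --out-json table.json --one-way oneway.csv

# generate a synthetic labelled cohort
sbtriage simulate --mode mechanism --n 5000 --seed 1 --out cohort.csv
```

Cohort files are plain CSV with canonical column names
(`age, atherosclerosis, ckd, antiplatelet, albumin, ..., mural`); model
files are JSON (`intercept`, `coef_*`, `cutoff_percent`); decision-model
parameters are JSON or YAML keyed like `sbtriage.cea.CeaParameters`.

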