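# phmri

Multiparametric MRI analysis pipeline for predicting parenchymal hemorrhage
(PH) after reperfusion therapy in acute ischemic stroke.

The package implements, end to end on synthetic cohorts:

* **DSC perfusion quantification** (`phmri.perfusion`) — signal to ΔR2*
  conversion, two-regressor leakage fitting (K2 permeability, a
  dimensionless decimal fraction), leakage-corrected contralateral-normalized
  CBV ratio, and Tmax by truncated-SVD deconvolution.
* **Lesion features** (`phmri.features`) — translation-only
  mutual-information registration, DWI z-score lesion VOI extraction
  (largest 26-connected component), 10th-percentile CBV/ADC and
  90th-percentile K2 over the VOI, infarct-core volume
  (ADC < 600 ×10⁻⁶ mm²/s), Tmax ≥ 6 s lesion volume, and the ≥90 %
  global-reperfusion rule.
* **Predictive models** (`phmri.models`) — the published fixed-coefficient
  logistic score `1.75 − 9.526·CBV10 + 2.7924·K2_90` (PH iff score ≥ −1.45),
  the published two-threshold classification tree (CBV10 at 0.47, K2_90 at
  0.28, configurable mixed-quadrant policy), backward-stepdown logistic
  regression by IRLS with Wald elimination, binary recursive partitioning
  with Gini splits, single-classifier threshold optimization, balanced
  accuracy ((sensitivity+specificity)/2), Mann–Whitney AUC, and Spearman
  feature correlations.
* **Synthetic cohorts** (`phmri.synthetic`) — gamma-variate bolus with
  recirculation and a leakage term, ellipsoidal ischemic core with depressed
  ADC/CBV and elevated K2, a contralateral normal-tissue reference region,
  and reproducible 83-patient cohorts (20 PH by default) with
  label-independent clinical covariates.
* **Pipeline & CLI** (`phmri.pipeline`, `phmri.cli`) — composable stages
  with NIfTI/CSV/JSON file contracts, manifests, and structured logs.

## CLI

```bash
phmri synth --out runs/synth --seed 1              # cohort table (+ --volumes)
phmri maps --dsc dsc.nii.gz --te 0.045 --dt 1.5 --baseline 5 \
      --ref-mask contra.nii.gz --out runs/maps     # CBV ratio, K2, Tmax
phmri features --cbv cbv_ratio.nii.gz --adc adc.nii.gz --k2 k2.nii.gz \
      --dwi dwi.nii.gz --brain-mask brain.nii.gz --contra-mask contra.nii.gz \
      --out features.csv
phmri predict --features features.csv --model published --out pred.csv
phmri evaluate --predictions pred.csv --out report.json
phmri run --config pipeline.json --seed 1          # all stages in one run
```

`phmri run` writes `cohort_truth.csv` (generating records),
`cohort_features.csv` (measured), `predictions.csv`, `report.json`,
`models.json`, `MANIFEST.json` and `run.log` into the configured output
directory; rerunning the same config and seed reproduces the cohort CSVs
byte-identically.

## Conventions worth knowing

* The decision at exactly a threshold counts as the PH side (logistic score
  ≥ −1.45; tree K2 ≥ 0.28, CBV < 0.47 per the printed split directions).
* Percentiles use linear interpolation between closest order statistics.
* Negative K2 values are retained, not clipped.
* The mixed quadrants of the two-threshold tree (low CBV + low K2, high CBV
  + high K2) are resolved by a configurable policy; the default falls back
  to the logistic score, alternatives are `root_cbv` and `majority_leaf`.
* The leakage fit is delay-sensitive: lesions simulated with a bolus-arrival
  delay yield biased K2/CBV (expected Boxerman-model behavior). Exact
  recovery holds on delay-free phantoms; set `lesion_delay_s=0` in
  `CohortConfig` for unbiased feature recovery.
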