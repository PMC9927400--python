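# rfa-radiomics

A tested, reusable pipeline for predicting immediate complete response (CR)
of CT-guided radiofrequency ablation of colorectal-cancer lung metastases
from paired pre-/post-ablation CT radiomics and clinical covariates.

The pipeline covers:

- **synth** — a synthetic study generator: ellipsoidal nodule / ablation-zone
  CT phantoms (Gaussian random-field texture with a class-dependent signal
  preset) plus a clinical cohort whose covariate marginals and outcome
  log-odds follow the published cohort tables (CA19-9 OR 1.007/U·ml⁻¹,
  right-lower-lobe OR 2.997, left-lower-lobe OR 2.498, non-CR prevalence
  100/479). Because the original imaging data is not deposited, this module
  is the test substrate for everything downstream.
- **preprocess** — 1 mm isotropic B-spline resampling, HU windowing
  [−1200, 600] → [0, 255], 40 mm cube cropping at the mask centroid, and
  per-cube min-max normalization.
- **features** — native radiomics features: first-order, shape, and
  GLCM / GLRLM / GLSZM / GLDM / NGTDM texture families (13-direction merged
  aggregation, 32-bin equal-width discretization, log₂ entropies), verified
  against exhaustive brute-force oracles.
- **select** — the five mRMR criteria (MID, MIQ, FCD, FCQ, RFCQ) with greedy
  forward selection and top-5/10/15 frequency consensus, with the set size
  chosen by inner 5-fold CV AUC.
- **split** — GMM cluster-stratified division into 5 groups (own EM with
  k-means++ init, BIC model selection), one group held out as the test set.
- **models** — univariate (p < 0.1) → multivariate (p < 0.05) logistic
  screening for the clinical model, SMOTE balancing of the training data,
  and seeded 500-tree random forests for both modalities.
- **fuse_eval** — decision-level fusion
  `confidence = ω₁·confidence_image + ω₂·confidence_clinical`, the ω-grid
  scan, Mann–Whitney AUC, the DeLong test for correlated ROC curves, and
  ACC / sensitivity / specificity.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` runs the acceptance criteria (texture-oracle
equivalence, mRMR arithmetic and recovery, screening parameter recovery,
DeLong type-I calibration, split contracts, fusion behavior, null safety,
and the published-arithmetic targets). The full suite takes ~15–20 minutes on
one CPU; the null-safety criterion alone simulates 50 end-to-end cohorts.

## CLI

```bash
# generate a synthetic cohort (NIfTI volumes + clinical CSV + manifest)
rfa-radiomics simulate --out cohort/ --seed 17 --n-lesions 479

# preprocess + extract the radiomics feature table from a cohort directory
rfa-radiomics extract --in cohort/ --out features/

# full pipeline: simulate -> extract -> split -> select -> train -> evaluate
rfa-radiomics run-all --out run/ --seed 17
rfa-radiomics report --run-dir run/
```

`run-all` accepts a YAML config (`--config cfg.yaml`) overriding any
`RunConfig` field (cohort size, image geometry, texture preset, effect
scale, forest sizes, the consensus m-range, ...). Every run writes its
resolved config, per-stage artifacts (features.csv, rankings.csv, split.csv,
consensus.json, report.json, weight_grid.csv) and stage timings.

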