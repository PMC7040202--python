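# ctradiomics

A CT-radiomics prognostic pipeline for progression-free survival (PFS) in
TKI-treated stage IV NSCLC, built and validated end-to-end on synthetic
tumor phantoms with known ground truth.

Real studies of this kind extract hundreds of quantitative 3D texture
features from the segmented tumor volume of interest (VOI) on CT, discover
a sparse prognostic subset, and summarize it as a Cox *radiomic signature*
that stratifies patients into fast and slow progressors. The patient data
behind such studies are private, so this package ships a phantom simulator
that reproduces the statistical structure of such a cohort — CT-like
volumes whose tumor texture parameters drive the progression hazard — and
implements every analysis stage as tested, reusable code:

1. **I/O** — NIfTI/NRRD volumes, clinical and feature CSVs, JSON
   models/reports, with strict grid-compatibility checks.
2. **Phantoms** — ellipsoidal tumors with tunable texture variance σ²,
   correlation length ℓ and skewness γ; exponential PFS with hazard
   λ₀·exp(β·z) on the standardized texture parameters; uniform
   administrative censoring; an optional null cohort (β = 0) as the
   negative control.
3. **Features** — exactly **481** features: 13 shape + 9 channels
   (original + 8 undecimated coif1 wavelet sub-bands) × 52 per-channel
   features (16 first-order, 24 GLCM, 12 GLRLM; 32 gray levels, 13
   directions, distance 1, direction-averaged).
4. **Selection** — training-cohort z-scoring, Pearson redundancy pruning
   (|r| > 0.8), LASSO-Cox with the penalty chosen by 10-fold
   cross-validated partial-likelihood deviance, an events-per-variable
   check, and a 10-split stability analysis.
5. **Survival** — multivariate-Cox signature with a training-median
   cutoff, Kaplan–Meier curves, the Harrington–Fleming G-rho log-rank test
   (rho = 1), Harrell's C-index with bootstrap CI, IPCW time-dependent AUC
   at 183 days, hazard-ratio tables, clinical/combined model comparison,
   and chi-square baseline tests.

The core model: with selected (normalized) features *x* and Cox
coefficients *β̂*, the signature is the linear predictor *s = β̂ᵀx*;
patients with *s* above the training-median are called high-risk. The
package also exposes the published fixed scoring rule

    signature = 0.312 × (first-order minimum × cluster shade) + 0.602 × SRHGLE

as `published_signature`.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
63-patient cohort (plus a 105-patient null cohort) and write summaries to
`results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_extract_features.py     # 63 patients x 481 features
python 03_select_features.py
python 04_fit_signature.py
python 05_evaluate_signature.py
python 06_null_control.py
```

A run with the default seed prints, at the selection stage:

```
post-Pearson candidates: 135
chosen penalty: 0.2440
selected features:
  ...
  LLL_glcm_cluster_shade: +0.5290
```

and at evaluation:

```
train:      n=31 events=19 C-index=0.885 (95% CI 0.795-0.957) AUC(183d)=0.948 log-rank p=0.0000
validation: n=32 events=19 C-index=0.710 (95% CI 0.565-0.836) AUC(183d)=0.715 log-rank p=0.0070
clinical model validation C-index: 0.514
combined model validation C-index: 0.686
null cohort n=105: G-rho log-rank chi2=0.316, p=0.574
```

Read: the signature discriminates progression risk in the held-out half
(C-index 0.710, significant KM separation), texture features carry the
signal the clinical covariates lack, adding clinical covariates does not
improve on the signature alone, and the texture-independent null cohort is
*not* significantly stratified — the expected behaviour of a real
prognostic signature and its negative control.

The same pipeline is available as a CLI over one YAML config
(`ctradiomics simulate|extract|select|fit|evaluate|run-all --config cfg.yaml`);
every stage is idempotent and embeds the config hash and seed in its
outputs. Config keys mirror `ctradiomics.pipeline.PipelineConfig` (e.g.
`n`, `grid_shape`, `n_gray_levels`, `pearson_threshold`, `folds`,
`horizon_days`, `seed`).

## Layout

```
src/ctradiomics/    library: grids, io_formats, phantom, preprocess,
                    features, texture, selection, survival, pipeline, cli
analysis/           numbered narrative drivers of the demo study
scripts/            acceptance.py
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, conventions, parameter choices, limitations
```
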