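# dosiomics-ntcp

Dosiomics-based NTCP modelling of grade ≥ 2 late rectal bleeding (LRB)
after prostate radiotherapy, across fractionation schemes.

Radiotherapy toxicity models usually summarize the 3D dose distribution
into dose-volume histogram points. This package instead computes *dosiomic*
texture features on the planned dose inside the rectum contour and builds
logistic NTCP models from them, for hypofractionated (HF: 64.6 Gy / 19
fractions) and conventionally fractionated (CF: 78 Gy / 39 fractions)
cohorts. Because fraction sizes differ, voxel doses can first be expressed
as biological effective dose with the linear-quadratic model,

    BED = D · (1 + d / (α/β)),   d = D / n,

with α/β = 2 or 3 Gy for late rectal toxicity. It is aimed at outcome
modellers who want a tested, reproducible implementation of the full
pipeline: resampling, voxelwise BED conversion, 1-Gy gray-level
discretization, 42 texture features (histogram / GLCM / GLRLM / GLSZM /
NGTDM), bootstrap signature selection, and cross-fractionation evaluation.

## The modelling procedure

For a training cohort with binary outcome y (LRB grade ≥ 2), candidate
predictors are the 42 min-max-normalized dosiomic features (plus the
fractionation scheme code for combined HF+CF models). On each of B = 1000
bootstrap resamples:

1. univariable logistic screening — reject candidates with Wald p > 0.2;
2. collinearity pruning — repeatedly drop the less outcome-correlated
   member of the most Spearman-correlated pair until VIF ≤ 5;
3. backward elimination by the change-in-deviance χ² test at p = 0.01.

Candidates selected in ≥ B/4 resamples form the signature (with a
most-selected fallback); *previous abdominal surgery* is always added.
Coefficients are medians over B fresh bootstrap refits,
`logit P = β₀ + Σ βⱼ xⱼ + β_s·surgery`, and β₀ is refit by maximum
likelihood with slopes frozen. Models are evaluated by rank-based AUC,
calibration slope and calibration intercept (ideal 1 and 0).

Since no clinical dataset ships with the package, a synthetic-cohort module
generates tubular rectum masks, prostate-plan-like dose fields with steep
anterior-posterior gradients, covariates and logistic outcomes matching the
emulated trial arms (HF: n=325, ~17% events; CF: n=331, ~10% events), with
known ground truth for recovery testing.

## Worked example

```python
import numpy as np
from dosiomics_ntcp import dose as dp, features as ft, modeling as mdl
from dosiomics_ntcp import synthetic as syn

# one synthetic HF cohort: volumes -> BED(α/β=2) -> 42 features -> outcomes
spec = syn.default_spec("HF", n_patients=650, seed=11)
sc = syn.generate_cohort(spec)
print(sc.cohort.n_events, "events /", sc.cohort.n, "patients")

model, freqs = mdl.build_final_model(
    sc.cohort, list(ft.FEATURE_NAMES), n_bootstrap=200, seed=1
)
print("signature:", model.signature)
print("odds ratios:", {k: round(v, 2) for k, v in model.odds_ratios.items()})
report = mdl.evaluate(model, sc.cohort)
print(f"apparent AUC {report.auc:.3f}, "
      f"calibration slope {report.cal_slope:.3f}, "
      f"intercept {report.cal_intercept:.3f}")
```

prints

```
115 events / 650 patients
signature: ['LZHGE', 'SRE', 'LRHGE', 'abdominal_surgery']
odds ratios: {'LZHGE': 13.4, 'SRE': 0.14, 'LRHGE': 2.71, 'abdominal_surgery': 2.26}
apparent AUC 0.703, calibration slope 0.982, intercept 0.000
```

The generative model behind this cohort is
`logit P = β₀ + 4.0·LZHGE + 0.7·surgery`. The procedure recovers the
generative feature — LZHGE, large-zone high-gray-level emphasis, a
high-dose-region texture — at the head of the signature; the co-selected
SRE and LRHGE are run-length features correlated with it (dosiomic
features are heavily redundant, so correlated companions sharing the
signal are expected and also dilute the single-feature odds ratio). The
surgery odds ratio 2.26 sits near the true e^0.7 ≈ 2.01, and the refit
intercept makes the mean predicted probability equal the event rate,
hence calibration intercept 0 on the training data.

The full eight-model study (HF/CF × BED2/BED3/PhyD plus two combined HF+CF
BED models, evaluated on the designed train/test matrix) runs with

```bash
dosiomics-ntcp run-study --seed 1 --bootstraps 1000 --out results/study
```

writing per-model JSONs, a predictor table (median ORs and p-values), the
performance matrix (AUC / calibration slope / calibration intercept per
model and cohort) and per-candidate bootstrap selection frequencies.

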