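# Methods

## Problem and model

Late rectal bleeding (LRB) of grade ≥ 2 is a dose-limiting toxicity of
prostate radiotherapy. Its modelled probability — a normal tissue
complication probability (NTCP) — is linked here not to dose-volume summary
statistics but to *dosiomics*: texture features computed on the 3D planned
dose distribution restricted to the rectum contour. Because
hypofractionated (HF: 64.6 Gy / 19 fractions) and conventionally
fractionated (CF: 78 Gy / 39 fractions) arms deliver different fraction
sizes, doses are optionally expressed as biological effective dose before
texture analysis,

    BED = D · (1 + d / (α/β)),    d = D / n_fractions,

applied voxel by voxel with α/β ∈ {2, 3} Gy (plausible values for late
rectal toxicity; lower α/β means greater fraction-size sensitivity). Each
voxel's per-fraction dose is taken as its total dose divided by the
scheme's fraction count, the standard linear-quadratic convention for a
fixed plan delivered over n identical fractions.

The NTCP model class is logistic regression on a small signature of
normalized dosiomic features plus the binary clinical covariate *previous
abdominal surgery*, which is always forced into the final model:

    logit P(LRB ≥ 2) = β₀ + Σ βⱼ xⱼ + β_s · surgery.

## Pipeline

1. **Preprocessing** (`dose`): dose and rectum mask are brought onto a
   common grid and resampled to isotropic voxels (dose: cubic B-spline;
   mask: linear interpolation thresholded at 0.5). Negative B-spline
   overshoot is clipped to 0 Gy. The resampled grid is sized so every new
   voxel center lies inside the original center extent, keeping constant
   fields exactly constant.
2. **Representation**: physical dose (PhyD) or BED at α/β = 2 or 3 Gy.
3. **Discretization**: masked doses are binned at 1 Gy into 1-based gray
   levels, `level = floor(D / w) + 1`, half-open bins with a closed top
   bin; the level count is the dose range in Gy rounded up to the next bin
   edge. The range is shared across all patients of a set — per cohort for
   PhyD, across both cohorts for each BED representation — so gray-level
   axes are comparable.
4. **Texture features** (`features`): 42 features — 3 histogram moments,
   8 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM. GLCM and GLRLM merge the 13 unique
   3D directions at voxel distance 1 by summation before normalization;
   GLSZM zones and NGTDM neighborhoods use 26-connectivity. Run percentage
   is computed from the merged matrix as N_r / (13 · n_voxels), identical
   to averaging per-direction ratios, so it stays in (0, 1]. Per cohort and
   representation, features are min-max normalized to [0, 1]; test cohorts
   are mapped with the training bounds and deliberately not clipped.
5. **Model building** (`modeling`): B bootstrap resamples of the training
   cohort each run (i) univariable logistic screening (reject Wald
   p > 0.2), (ii) collinearity pruning — repeatedly drop the less
   outcome-correlated member of the pair with the largest |Spearman ρ|
   until max VIF ≤ 5 — and (iii) backward elimination by the
   change-in-deviance χ² test (1 df) at 0.01. Features selected in ≥ B/4
   resamples form the final signature (if none qualify, the single most
   selected feature is used); abdominal surgery is appended; final-signature
   members with VIF > 5 on the full data are pruned by the same pair rule.
   Final coefficients are medians over B fresh bootstrap refits (median
   Wald p is reported alongside); the intercept is then refit on the full
   training data by maximum likelihood with slopes frozen, which makes the
   mean predicted probability equal the observed event rate.
6. **Evaluation**: discrimination by rank-based AUC (ties counted half);
   calibration slope from a logistic regression of the outcome on the
   model's linear predictor, and calibration intercept
   (calibration-in-the-large) with the linear predictor entering as an
   offset with coefficient fixed at 1.

The full study (`study`) builds eight models — HF and CF separately at
BED2/BED3/PhyD plus two combined HF+CF BED models with the fractionation
scheme code (1 = HF, 0 = CF) as an extra candidate — and evaluates them on
a fixed train/test matrix: separate BED models apparent + cross-scheme,
combined models on their HF and CF training subsets separately, physical
dose models apparent-only.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `bin_width` | 1 Gy | gray-level width; 1 Gy makes levels equal the dose range in Gy |
| `target_spacing` | 2 mm (synthetic), 1 mm supported | isotropic resampling grid |
| `alpha` | 0.2 | univariable screening threshold |
| `vif_max` | 5 | multicollinearity bound |
| `p_remove` | 0.01 | backward-elimination deviance-test threshold |
| `n_bootstrap` (B) | 1000 | bootstrap resamples for selection and for coefficient medians |
| signature threshold | B/4 | minimum selection count for final inclusion |

## Synthetic data generator

The generator (`synthetic`) stands in for an undeposited clinical cohort.
Per patient it builds a curved tubular rectum mask (radius ~11–14 mm,
length ~90 mm, seeded curvature/radius jitter; 26-connected by
construction; volume ~20–120 cm³) and a planned dose field with a sigmoid
anterior–posterior falloff anchored at the anterior rectal surface (~95%
of prescription there, ≲20% posteriorly; falloff scale 4.5 mm), perturbed
by seeded Gaussian hotspots and a smooth correlated noise field whose
amplitude (`heterogeneity`, default 1) drives between-patient texture
variation. Masked doses never exceed 110% of prescription.

Cohort-level defaults mirror the emulated trial arms: 325 HF patients
(target event rate 56/325 ≈ 17.2%, surgery prevalence 82/325 ≈ 25.2%) and
331 CF patients (33/331 ≈ 10.0%, 91/331 ≈ 27.5%). Outcomes are drawn from
a logistic model on *normalized* features — so generative coefficients are
directly comparable to recovered ones — with default generative signature
{LZHGE: 4.0, abdominal_surgery: 0.7}. LZHGE (large-zone high-gray-level
emphasis) is used because high-dose-region features of that kind are the
biologically expected drivers of LRB; its coefficient is set so the
standardized effect (β × SD ≈ 4 × 0.175) is ≈ 0.7. The intercept is
solved on the realized cohort so the expected event rate matches the
target exactly.

What the generator does *not* emulate: real planning-system dose textures
(beam arrangements, DVH constraints), inter-patient anatomy beyond tube
geometry, delineation variability, and any non-logistic outcome mechanism.
Passing recovery/null tests therefore demonstrate correctness of the
*procedure* under its own model class, not clinical validity of dosiomic
LRB prediction.

## Numerical choices and degenerate inputs

* Logistic fits use an in-package Newton–Raphson/IRLS solver (tens of
  thousands of small fits per model run); univariable screening is solved
  for all candidates simultaneously by a batched 2-parameter Newton
  iteration. Non-convergent multivariable fits are ridge-stabilized
  (λ = 1e-4) and flagged.
* Screening treats (quasi-)separated candidates (|slope| > 30 on
  normalized predictors, where the Wald p is unusable) as p < α: retained
  and flagged. Constant candidates carry no information and are rejected.
* VIF is the diagonal of the inverse correlation matrix; numerically
  singular sets get VIF = ∞. Pair-drop ties (equal outcome correlation)
  drop the lexicographically later name.
* The fallback "most selected" tie-break uses the smaller full-data
  univariable p, then name order.
* Bootstrap substreams are keyed (seed, stage, b, attempt): changing B
  never reshuffles earlier resamples, and single-class resamples are
  redrawn rather than skipped so B effective samples remain.
* Degenerate texture conventions: a single occupied gray level gives GLCM
  Correlation 0, NGTDM Contrast/Busyness 0; Coarseness and Strength
  denominators carry an ε = 1e-6 guard; constant histograms return
  skewness/kurtosis 0 (kurtosis is otherwise non-excess). Entropy uses
  log₂.
* A constant linear predictor evaluates to AUC 0.5 with calibration slope
  reported as 0 and a warning.
* Discretization errors out if a masked voxel exceeds the declared range
  rather than silently clipping.

## Problem sizes

Full-cohort runs use a 48×36×36 voxel grid at 2 mm spacing resampled
isotropically at 2 mm (the package's desk-scale default; 1 mm and larger
fields of view are configuration options). The test suite runs the
parameter-recovery experiment at n = 650 patients with B = 200 over 50
replicates structured as five independent cohort geometries × ten outcome
draws each — recovery probability depends on the realized feature
correlation structure, so replicates must span geometries, while drawing
outcomes fresh per replicate keeps the experiment affordable — and the
full study at B = 100; `scripts/acceptance.py` runs the study at the
procedure's reference B = 1000 and recovery over 4 × 5 replicates.

## Known limitations

* The exact 8-member GLCM feature set follows common radiomics convention
  (and must include VarianceGLCM); other conventions exist. The set is a
  single tuple in `features.py` and easy to swap.
* DICOM support assumes axial, identity-orientation RTDOSE grids and
  planar RTSTRUCT contours; oblique orientations are out of scope.
* Calibration of generator event rates is exact in expectation only;
  realized rates fluctuate binomially.
* Normalization bounds are carried from training to test cohorts (a config
  choice); refitting bounds per cohort would change cross-scheme results.
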