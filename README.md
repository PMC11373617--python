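# psma-multiomics

Multiomics machine learning for predicting the whole-mount ISUP grade
risk group of prostate cancer (high: grade group ≥ 3; low: < 3) from
PSMA-PET radiomics, whole-exome pathway genomics, immunohistochemistry
(IHC) pathomics, clinical covariates, and the biopsy ISUP grade — with a
synthetic cohort generator so that every stage is testable without any
patient data.

The package is aimed at methodologists working on small-cohort
multiomics classifiers who need the full evaluation chain to be
leakage-free and auditable.

## What it computes

**Feature engineering**

- *Genomics*: per-variant pathogenicity metascore
  `M_v = mean(EVE, CADD_norm, PolyPhen)` over the available scores, with
  CADD min-max normalized over the cohort; gene disruption
  `D_g = Σ_v M_v`; pathway disruption `D_p = Σ_{g∈p} D_g`; TMB =
  variants / Mb of sequenced territory; CNV burden = |∪segments ∩
  ∪regions| / |∪regions| ∈ [0, 1].
- *Radiomics* (2 mm isotropic B-spline resampling, 0.3-SUV fixed bins):
  SUVmin/max/mean/peak, PSMA-TV, TL-PSMA = SUVmean × PSMA-TV; IBSI-style
  first-order and GLCM features (13 3D directions, symmetric, averaged),
  including GLCM Joint Energy = Σ p(i,j)².
- *Pathomics*: modified H-score = 1·%weak + 2·%moderate + 3·%strong
  (0–300), averaged and maximized over tumor cores per marker; Gleason
  patterns → ISUP grade groups → the binary risk label.

**Evaluation**: 100-fold stratified Monte Carlo cross-validation
(70/30), with the >30% missingness filter, distance-weighted kNN
imputation, z-scoring, mRMR feature selection (mutual-information MID
criterion), random-search tuning of five classifier families (kNN, RF,
XGB, SVM, logistic regression) and isotonic calibration all fitted
strictly on each training fold.

**Explainability**: permutation importance (per feature and per
category), Monte Carlo Shapley values, and a depth-limited surrogate
decision tree with a fidelity AUC against the reference model.

## Worked example

```python
import psma_multiomics as pm

# a 65-patient cohort with three planted 1.5-SD effects
cfg = pm.CohortConfig(
    seed=11,
    effect_map={"rad::glcm::JointEnergy": -1.5,
                "rad::firstorder::Maximum": 1.5,
                "clin::psa_serum": 1.5},
    bx_informative=False,
)
table = pm.cohort_design_matrix(pm.generate_cohort(cfg))   # 65 x 203
summ, folds = pm.run_experiment(
    table, pm.PipelineConfig(algorithm="rf", n_folds=30, search_budget=4, seed=5)
)
print(round(summ.metrics_mean["AUC"], 3))
print(summ.selection_frequency.head(2))
```

prints

```
0.798
rad::glcm::JointEnergy      0.833333
rad::firstorder::Maximum    0.733333
dtype: float64
```

i.e. the pipeline recovers the planted signal well above chance (a
label-null cohort scores ≈ 0.53 on the same protocol) and selects the
planted features most often. The numbers are exactly reproducible for a
fixed seed.

The `analysis/` scripts run the stages as a narrative: `01` simulates
and writes the cohort, `02` assembles the 203-feature design matrix and
reports the missingness exclusions, `03` produces the cohort-comparison
table (rank-sum / chi-square), `04` benchmarks the five algorithms
against the biopsy-grade-only baseline, `05` explains the final RF model
(importances, Shapley values, surrogate flowchart), `06` runs the
omics-block ablations. Each writes its tables under `results/`.

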