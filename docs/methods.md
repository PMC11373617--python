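# Methods

## Problem and model

The package predicts the binary risk group of prostate cancer at radical
prostatectomy — whole-mount ISUP grade group ≥ 3 ("high") versus < 3
("low") — from a multiomics feature table: clinical covariates, PSMA-PET
radiomics, whole-exome pathway genomics, immunohistochemistry (IHC)
pathomics, and the biopsy-derived ISUP grade (bxISUP). Five classifier
families (kNN, random forest, gradient-boosted trees, SVM, logistic
regression) are evaluated under stratified Monte Carlo cross-validation,
and the fitted models are interrogated with permutation importance,
Monte Carlo Shapley values and a surrogate decision tree.

The canonical design matrix has 203 columns: 13 clinical, 113
radiomics-wide (107 texture/shape/histogram features plus 6 conventional
SUV metrics), 53 genomics (51 pathway-disruption scores + TMB + CNV
burden), 23 pathomics (11 markers × {average, maximum H-score} + the
TMA-core Gleason grade), and bxISUP.

## Feature engineering

**Genomics.** Each somatic variant carries up to three pathogenicity
scores: EVE and PolyPhen (already on [0, 1], used unchanged) and CADD
(scale-free; min-max normalized over all of the cohort's variants; a
degenerate range maps to 0). The variant *metascore* is the unweighted
mean of the available scores. Gene disruption is the sum of metascores of
the gene's variants; pathway disruption is the sum of gene disruptions
over the pathway's gene set (a gene in k pathways contributes to all k).
Variants with no score are excluded from disruption sums but still count
toward TMB, which is defined purely as variants per megabase of the
sequenced territory. CNV burden is the length of the union of CNV
segments intersected with the union of sequenced regions, divided by the
length of the region union; the merge-then-intersect order guarantees a
ratio in [0, 1]. All intervals are 0-based half-open (BED convention).
Open design points — whether EVE/PolyPhen should also be renormalized and
whether the combination should be weighted — are left as configuration;
the defaults are the simplest self-consistent reading.

**Radiomics.** SUV volumes are resampled to 2 mm isotropic voxels (cubic
B-spline for intensities, nearest-neighbor for the mask) and discretized
with a fixed bin width of 0.3 SUV referenced to the in-mask minimum, so
bins are invariant to uniform SUV shifts. Conventional metrics:
SUVmin/max/mean over the mask, PSMA-TV as mask volume, TL-PSMA =
SUVmean × PSMA-TV, and SUVpeak as the largest mean SUV in a 1 ml sphere
centered on an in-mask voxel (PERCIST convention; spheres truncated at
the grid boundary average over the valid part). GLCM features use
distance-1 co-occurrences over in-mask voxel pairs in the 13 unique 3D
directions, symmetrized, normalized per direction, features averaged over
directions — the IBSI aggregation default. First-order features use
population moments; on a zero-variance VOI, skewness and kurtosis are
reported as 0 (with a warning) to keep the table numeric. The in-repo
extractor covers the result-critical families (SUV metrics, first-order,
GLCM); the remaining texture families can be supplied by any
IBSI-compliant engine through `register_full_set_extractor` behind the
same `rad::<family>::<name>` column contract.

**Pathomics.** The modified H-score is 1·(%weak) + 2·(%moderate) +
3·(%strong), range 0–300; the unstained remainder carries weight 0. Per
patient and marker, the mean and maximum over available *tumor* cores are
the features; normal cores never enter, and a patient-marker pair without
tumor cores becomes a missing value for downstream imputation. Gleason
patterns map to ISUP grade groups (3+3→1, 3+4→2, 4+3→3, GS 8→4,
GS 9–10→5); risk is high iff grade ≥ 3.

## Evaluation engine

Monte Carlo cross-validation draws independent stratified 70/30 splits
(default 100). Per-class training counts round to the nearest integer,
with the larger class adjusted by ±1 to hit the rounded total — at
n=65 (28 low / 37 high) each training fold has 46 patients (20 + 26).

Within every fold, fitted on the training partition only:

1. **Missingness filter** — drop features with a training missing
   fraction strictly above 0.30.
2. **kNN imputation** — k = 5 donors from the training block,
   1/distance weights. Because imputation precedes z-scoring, distances
   are computed on internally min-max-scaled features (train min/max) to
   keep the Euclidean metric commensurable; the scaling is undone after
   imputation and observed values pass through untouched.
3. **Z-scoring** — train means and population SDs; constant training
   columns map to zeros with a warning.
4. **mRMR selection** — greedy forward selection under the MID
   criterion: relevance is the mutual information between feature and
   label, redundancy the mean MI with already-selected features, both
   estimated after equal-frequency discretization into min(5, ⌊n/5⌋)
   bins. Ties resolve to the earliest column, making the ranking
   deterministic. The greedy ranking is nested, so the selected-feature
   count is exposed as a tunable hyperparameter (grid {4, 8, 16} by
   default; the whole-dataset final model fixes k = 8).
5. **Random-search tuning** — configurations sampled from documented
   per-algorithm grids, scored by mean AUC over 3 inner stratified
   splits of the training fold, winner refit on the full training fold.
   A budget of 1 skips the inner search and uses the single sampled
   configuration.
6. **Isotonic calibration** — the monotone map is fitted on
   *out-of-fold cross-predicted* training scores (stratified 3-way
   partition; each part scored by a model fitted on the other two).
   This keeps calibration scores honest while letting the final model
   use the whole training fold. A vanishing raw-score admixture (1e-6)
   makes the map strictly increasing so isotonic plateaus cannot
   collapse distinct ranks into ties; calibrated AUC therefore equals
   raw AUC exactly.
7. **Metrics** — AUC (midrank ties), and ACC/SNS/SPC/PPV/NPV at
   threshold 0.5 on calibrated probabilities; positive class = high
   risk. Fold summaries report means with percentile (2.5/97.5) 95%
   intervals; a run fails if more than 10% of folds are unusable.

SVM scores come from the decision function through a logistic squash
(probabilities would require internal cross-validation); all other
families provide probabilities directly. All randomness derives from one
master seed via counters.

## Explainability

Permutation importance is the baseline test AUC minus the mean AUC after
within-column permutation (default 10 repeats); a feature outside the
model scores exactly 0, and category importance is the unweighted mean
over each category's features. Shapley values use Monte Carlo permutation
sampling against a marginal background (random background row per sweep),
which satisfies additivity within Monte Carlo error. The surrogate
workflow fits a depth-limited decision tree to the reference model's
predicted labels on a 70% split and reports fidelity as the AUC of the
tree's probabilities against the reference predicted labels on the
held-out 30%, plus a plain-text decision flowchart. Training on predicted
labels (rather than probabilities) was chosen because the fidelity
statistic is then a genuine classification AUC; both choices are defaults
of this package, not claims about any external workflow.

## Synthetic cohort generator

The generator emulates the study conditions end to end: n = 65 patients,
57% high-risk prevalence, whole-mount ISUP drawn consistently with the
binary label, biopsy-style grades (bxISUP and the TMA-core Gleason grade)
derived through a confusion kernel with default concordance 0.70 and a
2:1 down- versus up-grading bias (the concordance value is a free
parameter, not an estimate). Per patient it draws: a variant table
(Poisson(30) variants over a 300-gene pool with Zipf-like recurrence,
EVE ~ Beta(2,2), PolyPhen ~ Beta(0.5,0.5), CADD ~ Gamma(2,8), each score
missing for ~15% of variants), CNV segments over a 30 Mb exome-like
territory, a 24³-voxel 2 mm SUV phantom with a spherical lesion
(lognormal lesion SUV, radius 6–10 mm, Gaussian noise SD 0.3), and
3 tumor + 3 normal IHC cores per marker whose staining percentages are a
clipped linear map of a patient-level latent expression. Image-read
clinical parameters default to 35% missingness, other clinical to 2%,
IHC cores to 5% dropout.

Labels are drawn first; features are generated conditional on the binary
label. `effect_map` plants standardized effects (difference of class
means in units of the within-class SD). On directly simulated columns
(clinical, the delegated radiomics set) the effect is exact in
expectation. On columns computed from raw data the effect is planted
upstream — extra pathogenic variants in a pathway's genes (calibrated
against the cohort's empirical pathway-score SD), shifts of CNV length
fraction, lesion SUV, or latent IHC expression — so the realized effect
size is approximate and slightly attenuated by the nonlinear scoring
chains. A label-null cohort additionally requires `bx_informative=False`,
which permutes the biopsy-style grades across patients: a
concordance-linked biopsy grade is predictive by construction and would
otherwise carry signal even with every planted effect at zero.

What the generator does *not* emulate: correlated radiomics feature
blocks from a shared reconstruction, batch effects between IHC staining
runs, linkage between pathways sharing driver genes, realistic gene-panel
structure, or scanner-specific SUV bias. Passing tests therefore
demonstrate the correctness and leakage-freedom of the pipeline under
the stated statistical structure, not clinical performance on real
cohorts.

## Problem sizes of the shipped checks

The heavy property checks run the full pipeline at the study scale
(n = 65, 203 features): null calibration uses five replicate cohorts ×
100 folds with a single-draw search budget; signal recovery uses three
replicate cohorts (three planted features at 1.5 SD) × 50 folds with a
3-draw budget, plus permutation/Shapley audits of an 8-feature final
model. The analysis drivers default to 25 folds and small budgets;
fold counts and budgets are arguments, so study-scale runs (100 folds,
~20 draws) are one flag away.

## Known limitations

- mRMR mutual information is estimated without small-sample bias
  correction (the estimator is fixed by the discretization rule above);
  low-cardinality features therefore have slightly different bias than
  5-bin continuous ones.
- The random-search spaces are compact, documented defaults; they are
  not the result of a meta-optimization.
- Monte Carlo Shapley uses a marginal background and is exchangeable
  with tree-exact methods only in expectation.
- The SUV phantom is piecewise-constant plus noise; it exercises the
  extraction conventions (binning, directions, sphere averaging) but not
  realistic PET texture.
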