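# Methods

## Problem and data model

The pipeline predicts a binary KRAS mutation status per patient from
three grayscale tumor cuts (the slice with the largest tumor area and
its cranial/caudal neighbors), each with a binary mask delineating the
irregular tumor region `S`, plus a 9-value clinical record (liver and
lung metastasis, sex, age, tumor location code, T/N/M stages,
differentiation grade). Images and masks are 8-bit grayscale TIFFs tied
together by a CSV manifest; arrays are row-major with origin top-left,
and any nonzero mask pixel counts as in-ROI. A mask must contain at
least 16 pixels and images must be at least 8×8 (the minimum for a
3-level dyadic wavelet decomposition).

## Texture descriptors on irregular ROIs

Frequency-domain texture methods need rectangular support; everything
here is computed strictly inside `S`.

**Masked GLCM.** The co-occurrence matrix at distance d counts pixel
pairs with *both* endpoints in `S`, symmetrically. The raw count
matrices of the four orientations (0°, 45°, 90°, 135°) are pooled and
normalized once; this is the rotation-invariance averaging step, and
features are derived from the averaged matrix rather than averaged over
per-orientation features. Zero valid pairs (a too-small or fragmented
ROI at the requested distance) is an error, not a silent zero.

Gray levels are re-quantized per descriptor by linear min–max mapping of
the in-ROI range onto 64 bins (configurable). 64 levels keep a 64×64
matrix well populated for ROIs of a few hundred pixels; a constant ROI
maps to bin 0 by convention. Haralick coefficients use
energy = Σp², contrast = Σ(i−j)²p, homogeneity = Σp/(1+|i−j|),
correlation with marginal means/SDs (defined as 0 when a marginal
variance vanishes), entropy = −Σp ln p with 0·ln 0 = 0 (natural log).

**Uniform LBP.** 8 neighbors sampled by bilinear interpolation at
radius R; a neighbor at or above the center contributes a 1-bit;
patterns with ≤ 2 circular transitions are binned by their number of
1-bits (bins 0–8) and all others pooled in bin 9; the histogram is
normalized over valid centers. A center is valid only when the center
and every pixel touched by the 8 interpolations lie inside `S` — this
erodes the ROI by roughly R but guarantees tumor texture is never
contaminated by background. A constant region yields the all-ones
pattern, i.e. all mass in bin 8.

**Wavelets.** 3-level 2-D DWT with the Haar filter (shortest support,
hence least leakage across the mask edge; Daubechies-4 available via
the `wavelet` argument), periodized so subband sides halve exactly. The
mask is downsampled once per level with an "any pixel of the 2×2 block"
rule, which keeps small ROIs alive at depth (a majority rule would
extinguish thin structures). The DWT statistics vector takes mean,
energy (mean squared coefficient), entropy (64 equal-width bins over
the in-mask coefficient range, 0 for a constant region) and population
SD over 13 regions — the in-ROI original image plus the 12 subbands —
giving the documented 52 features. The hybrid descriptors reuse the
masked GLCM machinery on subbands: `WDCF` at d = 1 across levels
(f = LL: the three approximations, 3m features; f = All: all 12
subbands in level-major LL, LH, HL, HH order, 12m features) and `WCF`
on the four first-level subbands at d ∈ {1, 2, 3} (4m features). Their
exact lengths are this package's explicit, tested composition rules.

## Synthetic phantom cohorts

The generator emulates exactly the statistical structure the analysis
relies on, not CT physics:

- **Masks**: thresholded low-pass-filtered Gaussian noise (kernel width
  size/6, target area fraction drawn from 20–45%), keeping the largest
  8-connected blob; the central cut carries the full outline and the
  neighboring cuts an eroded copy, so the central slice has the largest
  area.
- **Texture**: white noise convolved with an isotropic Gaussian kernel
  of width w0 = 1 px for KRAS− and w0·(1 + texture_effect) for KRAS+,
  rescaled to 0–255. Class membership therefore changes only
  second-order gray-level statistics — which is all the descriptors
  measure. A per-patient log-normal kernel jitter (SD 0.05) makes cuts
  within a patient more alike than cuts across patients. w0 = 1 keeps
  the d = 1 GLCM structured but unsaturated at 64 levels.
- **Clinical**: metastasis indicators shift by `clinical_effect` on the
  log-odds scale (baselines: liver 0.30, lung 0.20); T/N stage and
  differentiation follow a proportional-odds model whose every
  cumulative log-odds shifts by the same amount — the exact ordinal
  analog of the dichotomous shift; M stage is 1 iff any distant
  metastasis was drawn. Sex, age (N(66, 9²), clipped to 30–95) and
  location (uniform over 4 site codes) are class-independent.
  Baselines are plausible for a metastasis-enriched colorectal-cancer
  cohort and are fixed constants of the generator.

With both effects at 0 the classes are identically distributed. All
outputs are pure functions of (EffectSpec, seed): each patient derives
its stream from (seed, patient index).

What the phantoms deliberately do **not** model: Hounsfield-unit
statistics, scanner noise spectra, slice-thickness effects,
inter-observer segmentation variability, and correlations between
clinical and texture signals. Passing tests therefore demonstrate that
the pipeline recovers class structure of the kind it assumes, not that
any particular kappa is attainable on real CT data.

## Classification protocol

- **Outer loop**: leave-one-patient-out; all cuts of the held-out
  patient are excluded from standardization, tuning and fitting.
- **Standardization**: per-feature zero mean/unit SD (population SD)
  fit on training rows only; constant features map to 0.
- **Inner tuning**: the training patients are shuffled into 5
  patient-grouped folds; every grid point is scored by the pooled
  voted predictions' kappa; ties go to the earliest (least complex)
  grid entry; a single-point grid skips inner CV. The inner protocol is
  this package's choice — the tuning values come from the published
  grids, but how they were searched was not specified.
- **Voting**: texture inputs give one prediction per cut and the
  patient label is the majority of the three; the clinical-only input
  is one vector per patient, so no voting applies. Combined inputs
  prepend the 9 clinical values to each cut's texture vector.
- **Scores**: the patient score for ROC/lift is the mean predicted
  KRAS+ probability over cuts; families without probability outputs are
  excluded from AUC reporting.
- **Seeding**: one master seed; fold f uses SeedSequence([master, f]),
  and experiment-grid cells derive seeds from (master, CRC32 of the
  cell id), so every cell and fold is independently reproducible.

**Classifier registry.** 34 specifications mirror the published
list — several families appear once per source-language row, each with
its own tuning grid (e.g. the perceptron hidden-layer rule
h1 = max(1, ⌊N/(I+C)⌋) resolved against the training data at tuning
time). All are backed by scikit-learn; the extreme learning machine
(random tanh features + ridge readout) and the kernel Fisher
discriminant (RBF kernel ridge on ±1 targets, its exact dual form) are
implemented in-repo as small estimators. Two mappings are
approximations by necessity: the conditional-inference tree is
represented as a depth-tuned CART (depth 1–5; the original
significance-based stopping has no scikit-learn analog), and the
recursive-partitioning tree uses CART with the conventional
minsplit = 20 / minbucket = 7 defaults. Boosting grids over the
ensemble size are evaluated from a single staged fit per inner fold,
which is mathematically identical to refitting each size (tested).

## Evaluation

Kappa, accuracy, sensitivity, specificity, precision, F1 in percent
from the patient-level confusion matrix; a metric with a zero
denominator is reported as undefined rather than 0; kappa of two
constant, equal raters is defined as 0 with a warning. ROC sweeps
"predict positive when score ≥ threshold" with tied scores grouped
(diagonal segments), AUC by trapezoid rule — equal to Mann–Whitney
concordance with half credit for ties. The lift chart reports the
fraction of positives captured versus the fraction of the cohort
targeted in descending score order, with the ideal envelope and the
random diagonal. Display rounding is half-up to one decimal.

## Problem sizes used in the test suite

Oracle-equivalence tests compare against exhaustive per-pixel coders on
100 random masked images up to 16×16 and against naive metric formulas
on 1000 random confusion matrices. Pipeline-level statistical checks
use full-size cohorts (56 patients, three 64×64 cuts): null calibration
averages LOPO kappa over 10 cohort seeds for a depth-tuned tree and the
AdaBoost ensemble; signal recovery averages 5 seeds for the
wavelet-Haralick descriptor with the recursive-partitioning tree
(texture_effect = 1) and for the clinical vector with AdaBoost
(clinical_effect = 2).

## Known limitations

- Leave-one-out evaluation of highly flexible classifiers on
  signal-free data exhibits a negative kappa bias (the training set is
  slightly depleted in the held-out patient's class, and
  noise-memorizing models anti-predict): an unpruned CART shows a mean
  LOPO kappa around −0.2 on null cohorts. Depth-regularized trees and
  the boosting ensemble stay near zero, which is why they anchor the
  null-calibration check.
- The gray-level quantization depth (64), homogeneity variant, entropy
  base and wavelet family were unspecified upstream; all are fixed,
  documented defaults and results shift with them.
- Categorical tumor location is encoded as a single integer site code
  to preserve the printed 9-value dimensionality; a one-hot encoding
  would change linear-model behavior.
- No missing-data handling: cohorts are assumed complete.
- Rankings across the full 1870-cell grid on phantoms do not transfer
  to patient data; only the qualitative properties (null calibration,
  signal recovery, dimensionalities, metric arithmetic) are claimed.
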