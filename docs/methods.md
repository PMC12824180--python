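# Methods

This document describes the statistical model, the preprocessing chain, the
model-selection criterion, the synthetic data generator, and the numerical
choices behind `sersml`. Nothing here is an empirical claim about real
patients; every number quoted is either a package default or a quantity the
package computes.

## Problem setting

The pipeline classifies surface-enhanced Raman spectroscopy (SERS) spectra
of cerebrospinal fluid (CSF), acquired on silver-nanoparticle (AgNP)
cellulose test strips, into two classes: control (label 0) and
hydrocephalus (label 1, the positive class). A spectrum is a vector of
intensities over the 550–1800 cm⁻¹ wavenumber range; one spectrum per
patient enters the analysis, so the train/test split is automatically
patient-level.

## Preprocessing chain

Each spectrum passes through four steps, in this order:

1. **Crop** to `[crop_lo, crop_hi]` = [550, 1800] cm⁻¹ (inclusive). The
   fingerprint region; wavelengths outside it carry mostly substrate and
   filter artifacts.
2. **Substrate subtraction.** The pointwise mean of a set of blank-strip
   spectra (default: 10 reference strips) is subtracted from the raw
   signal. Negative residuals are allowed at this stage — clamping here
   would bias the baseline estimate that follows.
3. **ALS baseline correction.** Asymmetric least squares
   (Eilers–Whittaker): iterate
   `z = argmin Σᵢ wᵢ(yᵢ − zᵢ)² + λ Σᵢ (Δ²z)ᵢ²` with `wᵢ = p` where
   `yᵢ > zᵢ` and `1 − p` otherwise, for `n_iter` sweeps. Defaults
   λ = 10⁴, p = 0.001, 10 iterations. The asymmetry makes the smoother
   hug the valleys (background) and ignore the peaks. The estimated
   baseline is subtracted and the result clamped at zero.
4. **L2 normalization.** Each corrected spectrum is scaled to unit
   Euclidean norm, removing overall intensity differences (droplet
   volume, focus, enhancement strength) while preserving band ratios.

### ALS numerics

The second-difference operator `D₂` is the natural (unpadded)
`(n−2) × n` matrix, so the smoother imposes no artificial boundary
conditions; straight lines are exact fixed points, which the tests assert.
The normal equations `(W + λ D₂ᵀD₂) z = W y` are assembled with
`scipy.sparse` and solved with a sparse direct solver per iteration. An
independent dense `numpy.linalg.solve` implementation of the same
equations serves as the test oracle; the two agree to 1 × 10⁻⁸ on
spectra up to length 500.

## Dimensionality reduction

- **PCA** (`svd_solver="full"` for determinism), at most
  `min(n_samples − 1, n_features)` components.
- **PLS** (PLS regression on the 0/1 label, `scale=False`), latent
  variables maximizing covariance between spectra and the class label.

Both are wrapped with a deterministic sign convention (the largest-magnitude
element of each loading is made positive) so that repeated fits are
bit-identical. Inside cross-validation the reduction is fitted on the
fold-training subset only; validation folds are transformed, never fitted —
the grid search accepts an instrumentation hook with which the tests assert
this leakage contract.

## Classifiers and hyperparameter grids

| Family | Features | Grid |
|---|---|---|
| LDA | PCA or PLS scores, 1–10 components | shrinkage ∈ {0, 0.25, 0.5, 0.75, 1⁻} |
| QDA | same | shrinkage ∈ {0, 0.1, …, 0.9} |
| SVM linear | same | C ∈ {0, 0.25, 0.5, 0.75, 1} |
| SVM poly-3 / RBF | same | C ∈ 10^{−3..3}, γ ∈ 10^{−6..1} |
| RF | full spectrum | trees ∈ {100, …, 1000}, min split ∈ {20,30,40,50}, min leaf ∈ {5,10,15,20}, max features ∈ {log2, sqrt, all} |

LDA and QDA are implemented directly as Gaussian discriminants with the
shrunk covariance `Σ(r) = (1 − r)Σ + r·(tr Σ / d)·I` (pooled for LDA,
per-class for QDA). This shrinkage target differs from scikit-learn's QDA
`reg_param` semantics, which is why they are hand-implemented; scikit-learn's
LDA (`lsqr` solver with shrinkage) is used as an independent oracle in the
tests. SVM and RF delegate to scikit-learn.

Two grid points deserve notes:

- **Linear SVM with C = 0** is ill-posed (the margin penalty vanishes).
  The grid retains the point; the search scores it −∞ and flags it as
  failed rather than silently dropping or "fixing" it.
- **LDA shrinkage 1** would collapse the covariance entirely; it is
  capped just below 1 (`1 − 10⁻⁹`).

### Random-forest grid sharing

For a fixed seed and fixed per-tree hyperparameters, the first `n` trees
of a scikit-learn forest are exactly the `n`-tree forest (tree-level
randomness is drawn sequentially from one seeded stream). The grid search
exploits this: per fold it fits only the largest ensemble of each
(split, leaf, features, depth) combination and scores every smaller
`n_trees` value from cumulative per-tree votes. The tests verify the
resulting fold scores equal independent refits. Majority votes are
resolved by `2·votes₁ > n`, so exact ties go to the control class — a
deliberate, documented convention.

## Selection criterion

For each grid point, stratified k-fold cross-validation (default k = 10)
on the training partition yields per-fold quantities, combined as:

- **WBA** (weighted balanced accuracy): over the classes, one-vs-rest,
  `WBA = Σᵢ ωᵢ · ½(sensᵢ + specᵢ)` with inverse-size weights
  `ωᵢ = (1/Nᵢ) / Σⱼ (1/Nⱼ)`. The index runs over *classes*, so minority
  classes count more; for two classes WBA reduces to the plain balanced
  accuracy ½(sensitivity + specificity) regardless of the weights.
- **MWBA**: the median of the k fold WBAs (mean of the central pair for
  even k). The median, not the mean, so one pathological fold cannot
  dominate.
- **Score = MWBA − λ·(TrainAcc − ValAcc)** with λ = 2, where TrainAcc and
  ValAcc are the mean fold-training and fold-validation accuracies. The
  penalty term punishes the train-validation gap that signals
  overfitting; λ = 2 makes one point of generalization gap cost two
  points of headline accuracy.

The winner is the strict argmax in deterministic enumeration order; ties
go to the earlier grid point.

### Split apportionment

The held-out test set has `ceil(test_fraction · N)` patients, apportioned
across classes by the largest-remainder rule on the class proportions.
For 70 controls + 47 cases at fraction 0.3 this gives test counts (22, 14)
and training counts (48, 33) exactly.

## Evaluation

The test partition is touched once, by the final evaluation stage:
confusion matrix (positive = hydrocephalus), accuracy, sensitivity,
specificity, precision, WBA, and a trapezoidal ROC/AUC (equal to the
Mann–Whitney pairwise probability, ties counted half; constant scores are
flagged degenerate with AUC 0.5). Undefined metrics (zero denominators)
are reported as NaN with an explicit flag, never as zero. If the winner
is a random forest, a per-wavenumber importance report (mean decrease in
impurity against the two class-mean spectra) is written, with the top
bands greedily selected under a 20 cm⁻¹ separation so adjacent grid
points of one band are not double-counted.

## Synthetic data generator

The generator emulates the two-class CSF-on-strip acquisition well enough
to exercise the full pipeline: class-differential Gaussian bands on a
substrate background with realistic variance structure. It is a study
condition, not a model fitted to data; its defaults were chosen once,
from the physical description of the assay, and are not tuned to any
downstream outcome.

One simulated spectrum is

```
spectrum = substrate_draw + patient_effect · s·peaks(class) + s·drift + noise,  clamped ≥ 0
```

- **Substrate**: a constant offset (0.5) plus four broad cellulose/AgNP
  bands (900, 1120, 1380, 1600 cm⁻¹; widths 45–70 cm⁻¹), multiplied by a
  strip-level and a position-level unit-mean lognormal factor.
- **Analyte peaks**: eleven Gaussian bands of width 8–10 cm⁻¹.
  Control-elevated: 600, 790, 900, 930, 1350 cm⁻¹ (the 900/930 bands are
  absent in the case class). Case-elevated: 710, 800, 1320, 1476, 1540,
  1690 cm⁻¹, with 800 and 1476 cm⁻¹ carrying the largest differential.
  Amplitudes are simulation parameters on an arbitrary scale.
- **Variance structure** (unit-mean lognormal multipliers):
  patient-to-patient CV 0.60, across-strip CV 0.055 (reproducibility),
  within-strip CV 0.012 (repeatability). The replicate-set API plus
  `cv_statistics` recover the latter two within 50% relative error in the
  acceptance tests.
- **Signal scale** `s` is calibrated so the expected sample mean
  intensity is `target_signal_ratio` (61.89) times the substrate mean —
  the strong plasmonic enhancement of analyte over blank strip.
- **Baseline drift**: a random low-order Chebyshev polynomial
  (amplitude 5, positive by construction), scaled with the signal — the
  slowly varying fluorescence/scattering background that the ALS step
  must remove.
- **Noise**: additive Gaussian, `noise_sd` = 0.2 on the substrate
  intensity scale, reflecting effective accumulation averaging (many
  co-added acquisitions); the final clamp at zero mimics detector
  flooring.

Two determinism details matter for testing: the random stream is consumed
identically for both class labels (so two spectra drawn with equal seeds
differ only at the differential bands), and a lognormal factor consumes
its draw even at CV = 0 (so switching a CV off does not shift every
subsequent draw).

### Grid density

The default axis has `n_points` = 313 over 550–1800 cm⁻¹, i.e. 4 cm⁻¹
sampling — matching the ~8 cm⁻¹ effective resolution of the portable
instrument class this assay targets (sampling at half the bandpass). It
also keeps the full-spectrum random-forest grid search tractable on one
CPU.

## Determinism

One master seed is expanded through `numpy.random.SeedSequence` into
named sub-seeds (`simulate`, `split`, `folds`, `classifier`), each below
2³¹ so it fits any downstream 32-bit seed parameter. Reruns of
`run-all` with the same seed produce byte-identical artifacts; the
acceptance suite asserts this by file comparison.

## Limitations

- The generator's band amplitudes, widths, and drift shape are plausible
  but arbitrary; it validates the pipeline's mechanics, not any clinical
  claim. Classification accuracy on synthetic data says nothing about
  diagnostic performance on real CSF.
- One spectrum per patient: the pipeline has no machinery for technical
  replicates inside the classification path (the replicate API exists
  only for CV characterization).
- The shrinkage discriminants assume class-conditional Gaussianity of
  the reduced scores; no goodness-of-fit check is performed.
- ROC curves on 36 test patients are coarse; AUC confidence intervals
  are not computed.
- With the default patient-to-patient CV of 0.60 and 117 patients, the
  held-out accuracy of the end-to-end pipeline varies noticeably with the
  simulation/split seed (roughly 0.86–0.94 observed on reduced grids);
  single-seed figures should not be over-interpreted.
- The ALS smoother's λ and p are fixed defaults, not optimized per
  spectrum; strongly curved backgrounds outside the simulated family may
  be under- or over-subtracted.
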