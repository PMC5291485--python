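# Methods

`gliotex` implements a classical radiomics pipeline for grading diffuse
gliomas on a single contrast-enhanced axial T1-weighted MR slice:
intensity features are extracted from a manually delineated tumor ROI,
combined in an unpenalized binary logistic regression, pruned by
backward elimination, and validated by leave-one-out cross-validation
(LOOCV).  Reader-style performance is summarized by the five confusion
indices, the empirical ROC area (Az), and paired DeLong comparisons.
This note records the model, the parameter choices, and the places where
the design was genuinely open.

## Feature model

**Global (histogram) features.** For the N in-ROI gray values
P_1..P_N the package computes population moments (divide by N, never
N−1):

    mean      = (1/N) Σ P_i
    variance  = (1/N) Σ (P_i − mean)²
    skewness  = (1/N) Σ ((P_i − mean)/σ)³
    kurtosis  = (1/N) Σ ((P_i − mean)/σ)⁴

Kurtosis is non-excess (a normal sample gives ≈ 3).  These are computed
on the *raw* intensities, before gray-level quantization, because the
moment definitions refer to pixel gray values, not bin indices.  A
constant ROI (σ = 0) sets skewness = kurtosis = 0 and flags the case
degenerate rather than propagating NaN into the classifier.

**Local (GLCM) features.** The ROI is re-binned to G gray levels
(default G = 64, a common radiomics compromise between co-occurrence
sparsity and discriminative resolution).  Binning is uniform-width over
the ROI's own [min, max] — i.e. per-case contrast normalization — with
right-closed bins: index = ⌈G·(v−min)/(max−min)⌉ − 1 clipped to
[0, G−1], so an interior bin-edge value falls in the lower bin, the
minimum maps to 0 and the maximum to G−1.  Co-occurrence matrices are
accumulated at distance d = 1 in the four standard directions (0°, 45°,
90°, 135°), counting only pairs with **both** pixels inside the mask,
symmetrically (both orders), and normalized to sum to 1.  Fourteen
Haralick-style features are computed per direction and averaged over
the four directions (arithmetic mean; the per-direction values are kept
in verbose output).  Entropies use log base 2 with 0·log 0 ≡ 0.

### Formula canonicalization

Several printed definitions of this feature set circulating in the
applied literature are internally inconsistent; the package implements
the canonical forms by default and exposes the literal printed variants
behind `formula_dialect="printed"` for auditability:

| feature | canonical (default) | printed variant |
|---|---|---|
| autocorrelation | Σᵢⱼ i·j·p(i,j) | duplicates the correlation formula |
| homogeneity | Σ p(i,j)/(1+\|i−j\|) | −Σ p(i,j)/(1+i−j): negative, asymmetric, undefined at j = i+1 (such cells contribute 0) |
| difference entropy | −Σ p_{x−y} log p_{x−y} | computed on p_{x+y} (i.e. sum entropy) |
| difference variance | Var of p_{x−y} | Σ k²·p_{x−y}(k) |
| inverse difference normalized | Σ p(i,j)/(1+\|i−j\|/G) | identical to homogeneity |

The printed difference variance deserves a remark: Σ k²·p_{x−y}(k) is
*algebraically identical* to contrast (contrast = Σₙ n²·P(|i−j| = n)),
so including both makes the feature matrix exactly collinear and every
unpenalized logistic fit singular.  The canonical variance of the
difference distribution is therefore the default
(`difference_variance="canonical"`); the printed form remains available
as a separate switch.  Similarly, the printed autocorrelation makes the
feature pool collinear with correlation, which is why
`formula_dialect="printed"` cannot be combined with a full-feature
unpenalized fit.

The information measure of correlation is IMC1 =
(HXY − HXY1)/max(HX, HY) with HXY1 = −Σ p(i,j)·log(px(i)·py(j)).

## Classifier

Unpenalized maximum-likelihood logistic regression (GBM = 1, the
malignant/positive class; LGG = 0) fit by Newton/IRLS on z-scored
features.  Convergence: max absolute coefficient step < 1e−8, cap 100
iterations.  Under perfect separation the likelihood has no finite
maximum; the fit returns its last iterate flagged non-converged — the
predicted probabilities are still usable (they saturate).  Exact
collinearity raises an error naming the dependent columns; constant
features are dropped with a warning.  Wald p-values from the inverse
observed information accompany every fit.

**LOOCV.** n refits, each leaving one case out, with the feature
standardization recomputed inside each fold so nothing leaks from the
held-out case.  Predictions use the radiologists' decision criterion:
malignant iff probability ≥ 0.5.

**Backward elimination.** Classic wrapper descent: starting from all 18
features, the removal with the lowest LOOCV misclassification rate is
applied at each step — even when the error ties or rises — down to one
feature, recording the whole trace.  Candidate sets whose design is
exactly collinear score +∞, so duplicated columns fall first.  Ties
between equally scoring removals are broken by the largest Wald p-value
in the current full-data fit (deterministic and conventional).  The
selected set is the globally minimal-error step of the trace; on ties
the smallest set wins, so redundant features whose removal leaves the
error unchanged are excluded.  A stop-at-first-non-improvement variant
was rejected because tied errors (the signature of a redundant feature)
would freeze the descent with the redundancy still in the model.

Selection is performed outside the LOOCV loop and optimizes the same
LOOCV error that is afterwards reported for the selected set.  This
mirrors the workflow the pipeline reproduces, but it is optimistically
biased; the full elimination trace is exposed so the optimism can be
audited, and nested validation is deliberately out of scope.

## Evaluation

Accuracy, sensitivity, specificity, PPV and NPV are exact integer-count
ratios; an index with a zero denominator is reported as undefined
(`None`), never as 0.  Az is the empirical (Mann–Whitney) area under
the ROC curve with ties counted ½ — a reproducible, distribution-free
substitute for binormal maximum-likelihood Az fitting, with which it
agrees closely for well-behaved rating data.  Paired reader comparisons
use DeLong's covariance-based two-sided test on correlated AUCs
(implemented from the midrank formulation; no installed package
provides it).  Contingency comparisons use the 2×2 chi-square without
continuity correction or Fisher's exact test.  Pooled misdiagnosis
rates divide the summed per-reader misses of a class by
(readers × class size).

## Synthetic phantoms

The generator emulates the imaging contrast that separates tumor
grades on contrast-enhanced T1:

* **LGG-like** — homogeneous: a Gaussian random field (white noise
  smoothed to correlation length 4 px, SD 40 intensity units) on a base
  intensity of 400 inside a mildly eccentric elliptical mask
  (radius ≈ ⅓ of a 64-px image).  Unimodal histogram, low local
  contrast.
* **GBM-like** — heterogeneous: a bright irregular enhancing rim
  (Gaussian radial bump at ≈ 0.72 of the ROI radius, amplitude 0.9 of
  base, rim radius modulated by low-order angular harmonics), a dark
  necrotic core (sigmoid drop to ≈ 25 % of base inside 0.45 of the ROI
  radius), and short-correlation-length speckle (1 px, SD 80).
  Bimodal histogram, high local contrast.

Gaussian random fields were chosen because the GLCM statistics of
interest (contrast, homogeneity, entropy) respond monotonically to the
correlation length, giving a controllable ground truth.  A single
`separability` knob linearly interpolates the GBM-like parameters
between the LGG-like values (separability 0: both classes share one
generating distribution) and the full values above (separability 1).
The knob is monotone but steep near zero: the necrotic-core term
switches on for any positive core fraction, so even small separability
values produce a detectable variance difference.  Cohorts default to
71 LGG-like / 34 GBM-like to mirror the clinical class imbalance the
pipeline is designed around; per-case radius
(±25 %), base intensity (±10 %), noise SD (±15 %) and smoothness
(±15 %) are jittered reproducibly from the master seed via
`SeedSequence` spawning.

What the phantoms do **not** emulate: MR acquisition physics (coil
bias, partial volume, k-space artifacts), anatomical surround,
infiltrative margins, and inter-rater ROI variability.  Passing tests
therefore demonstrate that the pipeline recovers *designed* texture
differences of the intended kind and magnitude, not clinical
performance on real MR images.  At full separability the phantom
classes are linearly separable in feature space, so end-to-end LOOCV
accuracy reaches 1.0 and elimination typically retains a single feature
— stronger than any real cohort would allow.

## Numerical choices and degenerate inputs

* Linear predictors are clipped at |η| ≤ 30 inside IRLS (the logistic
  saturates to machine precision well before); IRLS weights floored at
  1e−10.
* GLCM normalization is exact (counts divided by the pair total);
  property tests require the entries to sum to 1 within 1e−12.
* A constant ROI quantizes to all-zero levels, yields a single-spike
  GLCM (energy 1, entropy 0), zero marginal SDs — correlation and IMC1
  are then defined as 0 and the case flagged.
* A mask with no valid pixel pair at some offset raises an error naming
  the (d, θ) pair rather than emitting an empty matrix.
* Single-pixel ROIs are accepted with a warning.

## Problem sizes

Default test and reproduction sizes: 105-case cohorts (71 + 34) at
64×64 px for end-to-end runs; 1000 replicates for the DeLong null
calibration; 10 seeds for the noise-feature elimination check; 100
random matrices for the oracle-equivalence suites.  Property-style
simulations (null-separability AUC, monotonicity in separability,
direction-isotropy convergence) run at 45–60 cases over 3 seeds, sizes
chosen to keep the full suite comfortably fast while leaving the
statistical assertions well-powered.

## Known limitations

* One representative 2D slice per case; no 3D features, registration,
  or automatic segmentation.
* Feature selection is not nested inside the cross-validation
  (documented optimism, see above).
* The empirical Az and DeLong inference replace binormal MLE fitting;
  for heavily tied, coarse rating data the two can diverge.
* The printed-dialect variants exist for auditability, not for
  modeling: two of them collapse feature pairs into exact duplicates.
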