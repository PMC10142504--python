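# Methods

## Overview

The pipeline turns one co-registered case — a diffusion-weighted stack
(b = 0 and 1000 s/mm², 30 hemispheric directions), a DSC perfusion time
series (45 timepoints, TR = 2 s, TE = 45 ms), and a pre/post-contrast T1
pair — into a three-number feature vector from the contrast-enhancing
lesion and a predictive probability (PP) of tumor progression from a fixed
logistic model. Inputs are assumed motion/eddy-corrected and spatially
aligned; only grid reslicing is performed (trilinear for continuous maps,
nearest-neighbour for masks). Registration, distortion correction and
skull stripping are out of scope.

## Diffusion stage

The single-tensor model ln S = ln S₀ − b·gᵀDg is fit per voxel by
**unweighted log-linear least squares** — the simplest reproducible
estimator; a weighted fit is a config option but not the default. Voxels
with non-positive baseline or diffusion-weighted signal are excluded from
the validity mask rather than failing the fit. Eigenvalues are sorted
λ₁ ≥ λ₂ ≥ λ₃; negative eigenvalues (possible under noise) are clamped to
zero and counted, with the count surfaced on the result.

Scalar maps use the trace-normalized Westin convention:
MD = (λ₁+λ₂+λ₃)/3, FA = √(3/2)·‖λ−λ̄‖/‖λ‖, CL = (λ₁−λ₂)/T,
CP = 2(λ₂−λ₃)/T, CS = 3λ₃/T with T the trace. This convention keeps all
indices in [0,1] and gives the exact partition of unity CL+CP+CS = 1,
which the tests assert to 1e-12. The λ₁-normalized Westin variant would
change absolute CL/CP values by a bounded factor; the trace convention was
chosen for its testable invariant. Where T = 0 all indices are defined as 0.

## Perfusion stage

Signal is converted to ΔR2\*(t) = −ln(S/S₀)/TE with S₀ the mean over a
pre-bolus baseline window (default timepoints 0–7, configurable). Samples
where the signal reaches zero are capped at a configurable ceiling
(100 s⁻¹) and flagged. Bolus arrival is detected globally as the first
post-baseline timepoint where the in-mask mean ΔR2\* exceeds baseline mean
+ 3 SD (with a small absolute floor so a noiseless baseline still
thresholds).

Each voxel's first pass is fit with the gamma-variate model
C(t) = K(t−t₀)^α exp(−(t−t₀)/β) over the window from bolus arrival to the
first post-peak sample below 50% of peak. Truncating there excludes the
recirculation/leakage tail, which is the implemented leakage mitigation:
the tail never enters the fit, so a late-enhancing offset perturbs the
first-pass integral only weakly (tested at < 5% for a 5%-of-peak tail
offset). Initialization comes from the log-linearized form
ln C = ln K + α ln(t−t₀) − (t−t₀)/β solved by linear least squares,
refined by bounded nonlinear least squares. CBV is the closed-form
integral K·β^(α+1)·Γ(α+1) (arbitrary units); a non-converged fit falls
back to the trapezoidal integral of the truncated measured curve, flagged.
CBV never leaves the module un-normalized: rCBV is the ratio to the
**mean** CBV over the contralateral normal-appearing white-matter
reference ROI (mean rather than median — an undocumented detail in the
source protocol; mean is the default and the code takes any reference
statistic through the same path). CBV is only computed where it is
consumed (lesion ∪ reference) since the per-voxel fit dominates runtime.

## Lesion and reference ROIs

Enhancement is the relative difference E = (post−pre)/max(pre, ε) with
ε = 1e-6 of the pre-contrast median — invariant to joint affine intensity
rescaling, which the tests assert exactly. The threshold is
mean(E) + k·SD(E) over a normal-white-matter ROI (k = 3 by default;
exposed as `--k-sigma`); the lesion is the 6-connected supra-threshold
component containing the seed, with components under 5 voxels rejected.
The reference ROI mirrors the lesion across the grid midsagittal plane
(index i → Nₓ−1−i), removing lesion overlap and out-of-brain voxels; this
stands in for anatomical symmetry without atlas registration and requires
a configurable minimum size (50 voxels).

## Features and model

Features are medians over in-lesion valid voxels (voxels invalid in one
map are dropped from that map's statistic only). rCBVmax is read as the
**90th percentile** of the in-lesion rCBV distribution with the
linear-interpolation percentile definition; the "mean of the top decile"
reading is available behind `rcbvmax_mode="top10mean"`.

The classifier is PP = σ(β₀ + β₁FA + β₂CL + β₃rCBVmax) with fixed
published coefficients β₀ = −16.17, β₁ = 194.01, β₂ = −285.65, β₃ = 1.21,
stored as data (versioned JSON) rather than code. PP ≥ 0.5 ⇒ TP+mixed
(boundary inclusive on the progression side); the same inclusivity is
mirrored at the 25%-malignant-features histopathology boundary. PP is
computed through `scipy.special.expit`, safe for |logit| up to ~700.

`ProgressionClassifier` is a scikit-learn estimator. With coefficients set
(default) `fit` is label bookkeeping only; with `coefficients=None` it
refits the logistic model by unpenalized maximum likelihood, falling back
to a small ridge (λ = 1e-4) when complete separation is detected
(non-finite or > 1e4 coefficients). Leave-one-out cross-validation refits
per fold — the only reading under which a separately reported LOOCV
accuracy carries information beyond the plain concordance — and classifies
each held-out case at PP ≥ 0.5; folds whose training set lacks a class are
flagged and excluded with a reported count.

## Cohort statistics

The normality gate is a Lilliefors-style one-sample KS test; it is
advisory only — group comparisons always use the Mann–Whitney U test
(exact enumeration for pooled n ≤ 12 without ties, tie-corrected normal
approximation otherwise). Concordance between PP and the binary reference
is the point-biserial Pearson r (PsP = 0, TP+mixed = 1); Lin's concordance
correlation coefficient is available as an alternative but is not the
default, since a correlation "test" most directly means Pearson. ROC/AUC
uses TP+mixed as the positive class, ties credited ½ (the Mann–Whitney
formulation; tests verify equality with brute-force pairwise concordance
on small instances).

## mRANO rules

Tumor burden is the sum of products of perpendicular diameters (SPD).
Progression requires a ≥ 25% SPD increase over the nadir (the minimum of
all prior scans), persisting ≥ 25% above that nadir on a scan ≥ 28 days
later; an increase that settles below the threshold over the two most
recent consecutive scans — with the timeline long enough to satisfy the
4-week persistence rule — is pseudoprogression; anything else is
indeterminate. Both thresholds live in `MRANOConfig`, not in code.

## Synthetic data

**Phantoms** are a spherical lesion (radius 3.2 voxels, ≈147 voxels) in an
ellipsoidal brain on a 32×32×16 grid — only ROI summary statistics feed
the model, so geometric realism buys nothing. The lesion tensor is solved
*exactly* from the target (MD, FA, CL) triple: with the trace fixed and
λ₁−λ₂ pinned by CL, FA is monotone in the one remaining degree of freedom
and the root is found by bisection; infeasible pairs (FA below the prolate
bound ≈ 1.7·CL) raise. DWI is forward-simulated as S₀·exp(−b·gᵀDg); DSC
signal as S₀·exp(−TE·C(t)) with a shared gamma-variate bolus (t₀ = 20 s,
α = 3, β = 1.5 s) whose amplitude in the lesion is the planted
lesion-to-reference CBV ratio, so the planted rCBVmax is recovered
exactly at zero noise (uniform lesion ⇒ median = p90). T1 enhancement is
0.5 in the lesion over a faint deterministic ripple (amplitude 0.005)
that keeps the white-matter enhancement statistics non-degenerate.
Optional Rician (DWI) and Gaussian (DSC) noise are seeded and
deterministic. What phantoms do **not** emulate: partial-volume edges,
heterogeneous lesions, arterial input variability, susceptibility
artifacts, registration error — so a passing round trip demonstrates
algorithmic correctness, not robustness to real acquisition physics.

**Feature cohorts** draw (FA, CL, rCBVmax) per case from group-specific
truncated normals at the published group statistics (TP+mixed n=37:
0.14±0.03, 0.05±0.03, 4.09±1.85; PsP n=19: 0.11±0.02, 0.04±0.01,
2.49±0.97; FA, CL ∈ [0,1], rCBVmax ≥ 0). The stated mean/SD are treated
as moments of the *generated* features: the underlying normal parameters
are moment-matched to the truncation (per-margin root-finding on
truncated-normal moments), since plain truncation at zero would bias the
widest-relative-spread feature (TP+mixed CL) upward by ~7%. Features are
**independent by default** because only marginal statistics were
published; the correlation matrix is exposed for sensitivity exploration
but is deliberately not tuned.

### What the independence default implies

Two cohort-level bands are not reachable from the published marginals
alone, and the corresponding acceptance tests fail by design rather than
being weakened:

* **Point-biserial r ≈ 0.33** (published: 0.56). The CL coefficient
  (−285.65) converts the TP+mixed within-group CL spread (SD 0.03) into
  ≈ ±8.6 of logit noise, pushing PP toward 0/1 quasi-randomly within
  groups. In real tumors FA and CL are positively correlated (CL is a
  component of FA), and through the opposite-signed coefficients that
  correlation cancels much of this noise — but the joint distribution was
  never published, and guessing a correlation to hit the published r
  would be fitting the answer.
* **Mann–Whitney power for CL ≈ 0.14** at α = 0.05 (the published CL
  difference is reported significant at p = 0.04). The matched truncated
  distributions separate the group means by exactly the published 0.01
  with a right-skewed TP+mixed distribution, so the rank test has little
  to work with at n = 37/19.

The remaining bands are met: AUC ≈ 0.67 (band 0.65–0.90 around the
published 0.757), LOOCV ≈ 0.79 (band 0.61–0.85 around 73.2%), PP group
means ≈ 58%/27% (brackets around 61.3%/15.1%), Mann–Whitney power ≈ 0.98
(FA) and 0.95 (rCBVmax).

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
given it. The test suite and acceptance script use 300/200 synthetic
cohorts for the fast statistics, 20–30 cohorts for LOOCV, and 20
zero-noise phantoms for the imaging round trip — sizes at which the
Monte-Carlo error on each reported mean is well inside the band it is
checked against. Percentiles use linear interpolation between order
statistics throughout; report percentages are rounded half-up only for
display, with unrounded values retained.

## Known limitations

* Leakage mitigation is truncation-based; the optional Boxerman-style
  linear correction is not the default and the original study's exact
  (proprietary) correction is unobservable.
* Single-lesion analysis: the first seed-connected component only.
* The contralateral mirror assumes approximate head symmetry in the grid;
  heavily tilted acquisitions should be resliced first.
* The synthetic cohort's independence assumption understates the model's
  real-data concordance, as quantified above.
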