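# Methods

## Problem

After neoadjuvant therapy for locally advanced rectal cancer, the
decision between total mesorectal excision and organ preservation hinges
on lymph-node status, which radiologist restaging on MRI (ymrN) judges
poorly. The pipeline builds an image-derived score — a *radiomic
signature* — from the post-treatment tumour region on four co-registered
MR sequences (T1w, T2w, CE-T1w, ADC map) and combines it with the
radiologist's ymrT/ymrN stages into a logistic prediction model for
pathological node positivity (LNM+). Because the negative predictive
value is what licenses sparing surgery, the evaluation suite reports NPV
with exact binomial intervals alongside AUC and the comparison tests.

## Feature extraction

Extraction is 2D, on the single slice carrying the largest tumour
cross-section, using a binary ROI mask. Four filter channels per
sequence: the original image and scale-normalized
Laplacian-of-Gaussian responses at σ = 1, 2, 3 px (`LoG1`–`LoG3`,
reflect boundary). The truncated discrete LoG kernel is DC-corrected
(kernel minus its sum times a matching Gaussian) so constants map to
exactly zero. Per channel:

* **24 first-order statistics** — location, spread, percentiles, shape
  (population moments; skewness/kurtosis of a constant ROI defined as
  0), energy terms, and histogram entropy/uniformity in bits over the
  discretized ROI.
* **26 GLCM features** — symmetric, distance-1, four directions,
  averaged over offsets, normalized to sum 1; the standard contrast /
  correlation / cluster (shade = third central cross-moment) /
  sum–difference / information-measure set.
* **16 GLSZM features** — 8-connected zones of equal gray level,
  including LZLGE = Σ p(i,s)·s²/i².

Totals: 66 per channel, 264 per sequence, 1056 per patient. The
264-feature roster is the package's documented default; the per-class
composition (24 + 26 + 16) was chosen as the natural full set of
textbook statistics at that total, and the registry is parameterized if
a different roster is wanted.

Discretization is ROI-relative equal-width binning into 32 levels
(top bin right-closed; constant ROI → level 1). Consequences tested as
invariants: any increasing affine intensity rescale leaves all texture
features unchanged, and pixels outside the mask are irrelevant.

Inter-rater reproducibility uses the two-way random-effects,
absolute-agreement, single-measure ICC(2,1), computed from the two-way
ANOVA mean squares and vectorized across features; a feature with no
variance is reported as missing.

## Selection and modeling

All parameters are learned on the primary cohort only; the frozen
transforms are applied to the validation cohort (leakage is asserted by
test: corrupting validation rows changes nothing).

1. Unit-range normalization with primary-cohort min/max; validation
   values may fall outside [0, 1] (no clipping); primary-constant
   features map to 0 with a warning.
2. Wilcoxon rank-sum screen, two-sided, keep p ≤ 0.1 (inclusive). Exact
   enumeration when both groups have ≤ 25 members and no ties, midrank
   normal approximation with tie correction otherwise.
3. Spearman pruning at |ρ| > 0.9: pairs processed in descending |ρ|
   (ties by name pair), within a pair the larger screening p-value is
   dropped, pairs with an already-dropped member are skipped. This
   order makes the survivor set deterministic; the pruning rule itself
   does not prescribe one.
4. L1-penalized logistic path (binomial deviance), glmnet-style
   geometric grid of 50 λ from λ_max (smallest all-zero penalty) down
   to 0.01·λ_max, 10-fold label-stratified CV with seed-fixed folds.
   λ_1SE is the largest λ whose mean CV deviance is within one standard
   error of the minimum; the path is truncated early once the CV curve
   exceeds its running minimum by 3 SE for five consecutive grid points
   (λ_1SE ≥ λ_min, so the deep tail is never needed). Features are
   already on [0, 1], so no internal standardization is applied.

The signature is the linear predictor of a maximum-likelihood logistic
fit over the selected features; the predicted probability is its
logistic link (asserted identical to 1e-12). A univariate logistic
screen over sex, age, CEA, concurrent radiation, ymrT, ymrN and the
signature (Wald CIs; ordinal stages as numeric scores, so one odds
ratio per stage variable) selects the clinical covariates at p < 0.05;
the combined model is the joint fit of signature + significant stages,
the clinical model omits the signature. Perfect separation raises an
error advising the documented fallback, a small ridge penalty
(λ₂ = 1e-6) fitted without Wald inference; the pipeline applies the
fallback automatically and logs it.

### Nomogram

Each variable's points scale is `100·β_v·(x − x_ref,v)/M` with
`M = max_v |β_v|·range_v`, so the widest-impact variable spans 0–100.
The reference `x_ref,v` is the value minimizing `β_v·x` over the
variable's observed range — the variable minimum for positive
coefficients — which keeps all points nonnegative *and* makes total
points affine in the linear predictor, so the points→probability map
reproduces the model probability to 1e-9 (asserted on a grid). With a
plain "reference = minimum" convention a negative coefficient would
break that identity, which is why the low-risk end is used instead.

## Evaluation statistics

* **AUC** is the Mann–Whitney pair statistic (ties ½), asserted equal to
  brute-force pair counting to 1e-12. CIs and the correlated-AUC test
  use DeLong structural components; degenerate variance reports p = 1
  with a warning.
* **Youden cutoff**: maximizes sensitivity + specificity − 1 over
  observed-score midpoints, ties broken toward the higher threshold
  (higher specificity). Subgroup analyses derive the cutoff in the
  primary-cohort subgroup and freeze it for the validation subgroup.
* **Confusion metrics** carry Clopper–Pearson 95% intervals — an exact
  method chosen and documented here, since proportion CIs in this
  literature are often reported without stating the method.
* **McNemar**: exact binomial below 25 discordant pairs, continuity-
  corrected chi-square otherwise; no discordance gives p = 1.
* **NRI** is the category-free (continuous) version with the usual
  asymptotic z-test.
* **Hosmer–Lemeshow**: equal-size deciles of risk,
  χ² = Σ(O−E)²/(E(1−E/n_g)), default dof = groups − 2 (probabilities
  fitted on the data at hand). For externally supplied probabilities
  the correct large-sample reference is χ²(groups); `dof` is exposed
  for that case and the null-uniformity test uses it.
* **Decision curves**: NB(pt) = TP/n − (FP/n)·pt/(1−pt) against the
  treat-all and treat-none policies.
* **Cohen's kappa** unweighted; chance agreement of 1 is undefined
  (NaN).

## Synthetic cohorts

The study's patient data are private, so a generator supplies cohorts
with the statistical structure the analysis assumes — and nothing more.

Each patient gets one elliptical tumour mask (axes uniform in
[size/8, size/3], random centre and orientation; a filled ellipse is a
single 8-connected region) shared across sequences — perfect
co-registration, since registration error is not modelled. Each
sequence image is a unit-variance stationary Gaussian random field
(white noise smoothed at correlation length ℓ₀ = 2 px). Class signal is
injected only inside the mask:

* **intensity effect** — a mean shift of `intensity_effect` field-SD
  units for LNM+ patients (first-order features respond);
* **texture effect** — the in-mask correlation length becomes
  ℓ₀·(1 + texture_effect) for LNM+ (co-occurrence and size-zone
  features respond);
* the **T1w channel** has both effects pinned to 0, emulating an
  uninformative sequence; tests assert it rarely survives selection.

Between-patient heterogeneity is essential: texture features estimate
the correlation length almost noiselessly over a whole ROI, so without
it any nonzero effect separates the classes perfectly and the test bed
degenerates. Two heterogeneity terms are therefore part of the default
conditions: a per-patient, per-sequence ROI-mean offset with SD 1.0
(field-SD units) and a per-patient log-normal correlation-length
multiplier with SD 0.6. Under the default moderate effects (0.5/0.5 on
T2w/CE-T1w/ADC) the pipeline lands in the realistic radiomics regime —
validation signature AUC ≈ 0.78–0.86 at n = 391 — rather than at
ceiling. `CohortConfig.strong_effect()` (1.0/1.0) and `.zero_effect()`
give clearly detectable and absent signal for the recovery tests.

Clinical covariates: labels are exactly `round(n·prevalence)` positive
(default 87/391 ≈ 22%). ymrN reads reproduce a configured radiologist
sensitivity 0.563 / specificity 0.707 against the label, with the N1/N2
split of positive reads drawn from study-population fractions; ymrT is
drawn from stage distributions conditional on the label (positively
associated); sex, age, CEA and concurrent radiation are independent of
the label; cT/cN come from pooled marginals and are not used by the
screen. The 2:1 primary:validation split is stratified by label and
frozen at generation time. Everything is a deterministic function of
the seed.

What the generator does **not** emulate — MR physics, ADC computation
from b-values, registration error, inter-rater mask variability,
non-Gaussian lesion texture — bounds what passing tests show: they
validate the statistical machinery and its leak-free wiring, not
clinical performance on real images.

## Problem sizes and numerics

The replicated end-to-end checks run 20 strong-effect and 10
zero-effect full pipeline replicates at n = 400, 36 px images (the
package's chosen replicate size; the zero-effect chance band is asserted
on the mean validation AUC across replicates, whose Monte-Carlo SD is
~0.02, rather than per replicate where the null SD ~0.06 would trip the
band by chance). The default image size is 64 px. Logistic fits use
Newton iterations to tol 1e-10 (cap 200 iterations); liblinear L1 fits
use a loose tol (1e-4) along the CV path and 1e-7 for the final fit at
the chosen λ, with a fixed internal shuffle seed so selection is
bit-reproducible. Degenerate inputs follow documented conventions:
constant ROIs (level 1, zero moments), empty masks (errors naming the
cause), single-class subgroups (metrics reported missing with a
reason), and all-tied scores (Youden J = 0 with a warning).

## Known limitations

The exact 264-feature roster and LoG scales used by the original
clinical analysis are unpublished; the package's documented defaults
preserve the count and the class structure, not the private roster.
The signature's performance on the real cohort cannot be reproduced
without the private images; the verification machinery instead checks
every publicly derivable quantity exactly and the pipeline's behaviour
under controlled signal.
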