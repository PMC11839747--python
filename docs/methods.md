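# Methods

This note documents the models, conventions and design choices behind
`legmuscle`, in the order the pipeline uses them.

## Measurement model

The toolkit consumes a fat image F and a water image W on a shared voxel
grid (reconstructed fat/water separation is an input, not something this
package computes) plus an integer label map with the canonical encoding
1–5 = left anterior compartment, deep posterior compartment, lateral
compartment, soleus, gastrocnemius and 6–10 the same muscles on the
right. All computation happens in voxel space; the NIfTI affine is used
only for the voxel volume |det A₃ₓ₃|. Masks must already live on the
image grid — the package never resamples, because silent interpolation
would corrupt fat-fraction averages.

Per voxel, fat fraction is FF = 100·F/(F+W), defined where the total
signal exceeds a threshold `eps` (default 1e-12 × max(F+W), i.e. only
true signal voids such as air and cortical bone are excluded). Per
muscle:

* **Volume** uses the raw mask: voxels × voxel volume / 1000 (mL). It is
  invariant to image intensities by construction.
* **IMF** is the mean of per-voxel FF over the mask after one binary
  erosion with the full 3×3×3 (26-connected) structuring element, with
  array borders treated as background. Erosion trades volume for
  specificity: boundary voxels that overlap subcutaneous or intermuscular
  fat are removed before averaging, which substantially improves
  between-rater reliability of IMF. Volume is never taken from the eroded
  mask — erosion exists to decontaminate the intensity average, not to
  shrink the anatomy.

Two deliberately exposed alternatives: `imf_mode="signal_ratio"` computes
100·ΣF/(ΣF+ΣW) over the region instead of the voxel-mean FF (the two
differ in how they weight voxels; voxel-mean is the default because it
matches common fat-fraction ROI reporting), and `erode_for_imf=False`
disables the erosion. Erosion is applied per label independently, not to
the union mask, matching per-muscle reporting. The structuring element is
the full cube in *voxel* space; anisotropic voxels (0.71×0.71×5 mm) are
not compensated, so one iteration removes ≈0.7 mm in-plane and 5 mm
through-plane. This is a fidelity-over-geometry choice and is the main
reason IMF needs masks a few voxels thick per slice.

If an eroded mask is empty or holds no valid-signal voxels, IMF is
reported missing (never 0) and a warning is logged.

## Segmentation metrics

Candidate and reference label maps are scored one label at a time,
one-vs-rest over the full image domain: Dice = 2TP/(2TP+FP+FN), Jaccard,
conformity = 1 − (FP+FN)/TP ≡ (3·Dice−2)/Dice (undefined at TP=0,
reported missing), TPR, TNR, PPV and the volume ratio (candidate/reference
voxel counts). The TNR is computed over the whole field of view and is
therefore near 1 by construction in background-dominated images — it is
reported for completeness, not for discrimination. The only multi-label
aggregate is the unweighted mean across labels. All 0/0 cases are missing
values with warnings, never exceptions.

## Agreement statistics

ICC(2,1) — two-way random effects, absolute agreement, single measures —
is written out from the ANOVA mean squares,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),  k = 2,

so the variant is unambiguous: a constant offset between raters lowers
it, unlike a Pearson correlation, and it can be negative. Bland–Altman
reports bias = mean(d), limits of agreement bias ± 1.96·sd(d) with the
n−1 denominator, and a proportional-bias OLS of the difference on the
pairwise mean (the standard Bland–Altman regressor; regressing on one
arm's value is a documented alternative the package does not use).
Subgroup accuracy comparisons use the pooled-variance two-sample t-test
(appropriate for equal-size groups; a Welch switch is provided).
Strata with fewer than 3 complete pairs are reported missing.

## Association models

Standardized multiple regression z-scores the outcome and every predictor
with n−1 SDs; sex is coded female=0/male=1 and then z-scored like any
numeric column, so its coefficient is on the same standardized scale as
the others. Estimated marginal means by sex come from the unstandardized
model y ~ age + bmi + sex evaluated at sample-mean age and BMI with
delta-method SEs. Hierarchical fits add one muscle measure to the
age+BMI+sex base; ΔR² is tested with F_change = ΔR²·(n−p−1)/(1−R²_full)
on (1, n−p−1) df, which for a single added term equals the squared t of
that term. Partial Pearson correlations residualize both variables on the
controls and use t = r·√((n−2−k)/(1−r²)). Residual diagnostics are the
Shapiro–Wilk test plus a scale-location summary (Pearson r between fitted
values and √|standardized residuals|). Missing data are handled by
listwise deletion with logged counts. No multiple-testing correction is
applied across muscles; per-muscle p-values are reported at face value.
Left and right measures are modelled separately, each against the
same-side force. Ordinary least squares itself is delegated to
statsmodels; the standardization, ΔR² and EMM layers are this package's.

## Synthetic phantom

Each axial slice holds two circular legs: a subcutaneous fat ring
(default FF 90%) around a muscle annulus divided into five angular
sectors (the five muscle groups) surrounding a bone signal void. Default
geometry is 96×64×10 voxels at 0.71×0.71×5.0 mm. The leg radius tapers
linearly to 85% toward the inferior slices and the sector layout twists
slightly slice to slice, so one stack yields distinct cross sections;
optional superior slices contain air only, as stacks extending above the
muscle origin do. Default per-muscle fat fractions are 5, 8, 12, 15, 20%
(anterior → gastrocnemius), a plausible mid-adult ordering with the
posterior groups fattier. Sector angular width is proportional to the
per-muscle area scale; five sectors at scale 1 cover 75% of the annulus
and the remainder is unlabeled muscle-like tissue (FF 10%), reflecting
that not every leg muscle belongs to a segmented group.

In tissue the noiseless signals are F = S0·ff/100 and W = S0 − F
(S0 = 100), so FF recovers ff *exactly*, including in floating point —
this is what makes the exactness tests meaningful. Noise is additive
Gaussian per channel, clipped at 0. Dixon magnitude noise is not actually
Gaussian; this choice keeps the generator an analysable oracle while
still exercising robustness, and is one of the ways phantom results
understate real-data difficulty (see Limitations).

The simulated rater applies, per slice and per label with a configurable
probability, one 2D 3×3 dilation or erosion plus an integer shift, then
repaints labels in seed-randomized order without overwriting — masks stay
disjoint and the perturbation mimics boundary disagreement between
human raters.

## Cohort generator

Covariates follow a mid-adult observational cohort: age ~ N(34.2, 11.2²)
years, BMI ~ N(25.1, 4.5²) kg/m², 73.7% female; plantarflexion force is
centred at 122.5 Nm (SD 30). Outcomes are linear on standardized scales:
per muscle and side, z(volume) = 0.4·z(BMI) + 0.5·z(sex) + ε and
z(IMF) = 0.3·z(age) + 0.25·z(BMI) − 0.15·z(sex) + ε by default — volume
tracks body size and male sex but not age, IMF rises with age and BMI
and is slightly higher in females. Force is
z(PF) = −0.15·z(age) + 0.15·z(BMI) + 0.4·z(sex) + 0.32·z(soleus volume) + ε.
With unit-variance outcomes (residual SDs default to √(1−Σβ²)) the
soleus term contributes 0.32²·(1−0.41) ≈ 0.060 unique variance, i.e. a
ΔR² of about 6% beyond age+BMI+sex, and a full-model R² near 0.48 —
the regime where hierarchical-model recovery is worth testing. Volume
means per side (AC 270, DPC 110, LC 110, soleus 450, gastrocnemius
250 mL, SD 20%) and IMF means (6–10%, SD 2) are literature-plausible
adult values. Sex effects are standardized against the population split
p(male), not the sample split.

Requesting phantom images for a cohort scales each participant's sector
angles to reproduce the generated volumes (both legs share one sector
layout, so left/right volume targets are matched by their mean) and sets
sector fat fractions to the generated IMF; volumes that exceed the
annulus capacity raise an error naming the participant and muscle.
Because statistical-recovery work needs only the covariates and the exact
generating measures, image synthesis is off by default.

## U-Net harness

The segmentation network is a compact numpy implementation: residual
blocks (two 3×3 convolutions with instance normalization and LeakyReLU,
plus a projected skip), stride-2 downsampling, nearest-neighbour
upsampling with skip concatenation, a 1×1 classification head, combined
soft-Dice + cross-entropy loss, and AdamW. Convolutions are im2col
matmuls with an explicit col2im backward; a finite-difference test pins
the gradients. Everything — initialization and slice sampling — derives
from one seed, so training is bit-reproducible on CPU.

The default configuration mirrors a full-scale clinical setup (416×240
window, channels 64–1024, strides 2,2,2,2, AdamW at lr 1e-4 with weight
decay 1e-5, batch size 1); the deepest width is 1024, completing the
doubling pattern, with any literal width configurable. That configuration
is expressible but not what the tests run. The desk-scale configuration
(`TrainConfig.tiny()`) uses a 96×64 window, channels 8/16/32/64 with
strides 2,2,2 and 2000 iterations at learning rate 1e-3 with cosine
decay: narrow channels but full depth, because the deepest level's
receptive field must span a leg for the low-contrast sector boundaries
(adjacent fat fractions 3 points apart) to be resolved from angular
context, and the full-scale learning rate is needlessly slow at this
width. Training consumes the water image only (muscle borders
are water-signal structures); a fat+water two-channel mode exists as a
flag. Slices containing foreground are sampled with probability 0.9, any
slice otherwise: at batch size 1 some foreground bias is necessary, and
the air-only slices that remain teach the network to predict background
on empty input. Inference is per-slice argmax, center-padded to the
window and cropped back.

The desk-scale benchmark trains on five synthetic stacks (96×64×24, two
air-only superior slices, leg radius and per-muscle area scales varying
phantom to phantom, sectors tiling the full annulus as the real
compartments tile the leg) and scores two held-out stacks. Problem sizes
were chosen so the whole benchmark runs in minutes on one CPU.

## Numerical and degenerate-input conventions

* Grid compatibility: affines must agree within 1e-4 elementwise;
  mismatches raise, nothing resamples.
* Negative input intensities are clamped to 0 with a logged warning.
* ICC with fewer than 3 pairs, or zero total variance, raises; metric
  0/0s are missing values; partial correlation with a fully-explained
  outcome returns r=0, while a fully-explained predictor raises.
* SDs use the n−1 denominator throughout the statistics layer.
* CSV floats are written at 12 significant digits, which is what makes
  rerun byte-identity achievable.

## Known limitations

* The phantom is topologically, not anatomically, faithful: circular
  legs, angular-sector compartments, piecewise-constant fat fractions,
  Gaussian noise, no bias fields, motion, ghosting or fat-water swaps.
  Passing phantom benchmarks demonstrates the pipeline's correctness and
  the trainability of the network, not clinical-grade segmentation.
* Desk-scale structures are an order of magnitude smaller than clinical
  scans, so boundary discretization costs proportionally more Dice than
  it would at 448×266 resolution.
* IMF from 5 mm slices with a cubic erosion element loses whole slices
  from thin muscles; very small masks legitimately return missing IMF.
* ICC confidence intervals and >2 raters are out of scope; so are
  surface-distance metrics and any multiple-testing correction.
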