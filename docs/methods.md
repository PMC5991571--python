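# Methods

## The analysis model

`taskpca` implements a component-based analysis of event-related
sensorimotor fMRI.  One acquisition is a matrix **X** with one row per time
frame (224 frames at TR = 2 s by default) and one column per gray-matter
voxel, in a fixed x-fastest voxel ordering.  The analysis removes additive
structure by double centering,

    R[i, j] = X[i, j] − rowmean(i) − colmean(j) + grandmean,

so that every row mean, column mean and the grand mean of **R** vanish, and
decomposes **R** by singular value decomposition.  Each component consists of

* an **eigenimage** — the spatial loading pattern over masked voxels,
* an **eigenvariate** (temporal expression coefficient) — the component's
  unit-norm time course,
* a singular value whose square, divided by the sum of all squared singular
  values, is the fraction of variance the component describes.

Eigenvariates (and eigenimages) of one acquisition are orthonormal; the sign
of each component is fixed so its largest-magnitude voxel loading is
positive, and downstream logic treats the sign of correlations explicitly.

When voxels vastly outnumber frames the decomposition runs through the
frames × frames Gram matrix **R Rᵀ** (eigenimages recovered as `Rᵀu/s`),
which is algebraically identical to the direct SVD; the two paths agree on
singular values to 1e−8 on test problems.  Singular values below 1e−10 of
the largest (1e−7 on the Gram path, its numerical resolution) are treated as
rank-degenerate and dropped.

## Task-related component selection

The expected BOLD time course of a design is a boxcar of event on-periods
convolved with a double-gamma hemodynamic kernel (peak delay 6 s, undershoot
delay 16 s, unit dispersions, peak:undershoot 6, 32 s support, oversampling
factor 16, convolution truncated at the scan end), sampled at frame times
and mean-centered.  The correlation between an eigenvariate and this modeled
response is the **ecc**.  Testing all components of an acquisition at
family-wise level α means each must individually pass α/(n−2) under the
correlation t-test with n−2 degrees of freedom; the critical |r| is obtained
by inverting

    t = r · sqrt(df / (1 − r²))

at the Bonferroni-corrected tail probability.  For 224 frames at α = .01
this gives 0.269; for an 84-frame acquisition, 0.407.  Selection uses |ecc|
— an anticorrelated network is as task-related as a correlated one — and the
signed ecc is kept for weighting and interpretation.  The Kaiser–Guttman
screen (variance strictly above the mean component variance) is reported as
a diagnostic alongside the selection.

## Classification by volume correlation

Task-related components are assigned to one of two reference spatial
patterns by the **vcc**, the Pearson correlation of two images over masked
voxels.  Smoothing correlates neighbouring voxels, so vcc significance is
governed by an *effective* number of degrees of freedom, 1660 by default
(appropriate for ~151k voxels of 2 mm at 8 mm FWHM); the theoretical
critical |vcc| at p < .05 corrected for 240 comparisons is then 0.09, and
the conservative default threshold is 0.14 (at which the corrected p is
below 3 × 10⁻⁶).  `calibrate_null_vcc` re-estimates both for any other
geometry from simulated smoothed-noise images: the reciprocal of the null
vcc variance estimates the effective df (on test geometries it lands within
a factor of two of the resel count, volume/FWHM³ — about 0.83 of it for an
interior mask, with boundary truncation of the kernel pushing the ratio
up), and the suggested threshold is the larger of the theoretical value and
a high quantile of the observed null.

Four exclusion rules prune the assignments, in order: (1) below threshold
(neither |vcc| exceeds it); (2) ambiguous (both exceed it and differ by at
most `ambiguity_delta`, default 0.05 absolute — the comparability margin is
not defined more precisely by the underlying analysis, so it is exposed and
flagged); (3) redundancy (one component per acquisition and pattern — the
largest |vcc| wins, ties broken by component index); (4) cross-acquisition
inconsistency, operationalised as: a subject's two same-condition
acquisitions assign the pattern with opposite vcc signs, in which case the
weaker |vcc| is dropped.  Rule 4 is one reading of an underdetermined
bookkeeping rule; each component carries its exclusion reason so users can
override.

Survivors of each (condition, pattern) cell are averaged into a **mean
component image (MCI)** with weights |ecc|/Σ|ecc|, each contributor
sign-aligned to its reference first.  Both the image and the mean expression
coefficient are ecc-weighted by default; `weight_images=False` switches the
image to an unweighted mean (the weighting of images, as opposed to time
courses, is ambiguous in the source analysis).

## Second-level PCA

As a control against classification bias from reliance on reference
patterns, the task-related component images of one condition are stacked as
rows (unit-normalised; a no-op for eigenimages) and decomposed with the same
double-centered SVD.  Because the column means subtract the mean image, the
leading second-level component captures the dominant *scatter direction*
across images.  When the inputs mix the two anticorrelated networks, that
direction is the pattern-I-versus-pattern-II contrast, which correlates
strongly and with opposite signs with the two references.  Note a
consequence of double centering: a stack of images expressing one pattern at
*identical* amplitude has no pattern variance left after centering, so the
leading component would be noise; recovery of the pattern as PC1 requires
amplitude or composition variability across inputs (which real and
simulated data both have).  On the synthetic default study the PC1 variance
fraction differs between conditions, but its direction is data-specific and
is not asserted by any test.

## Group statistics

Condition comparisons follow the field's conventions: Mann–Whitney U
(exact when the smaller group has ≤ 12 observations and no ties, otherwise
the tie-corrected normal approximation) for ecc distributions; unpaired
pooled-variance Student t for vcc distributions; the Fisher z
transformation, `z = (atanh r₁ − atanh r₂)/sqrt(1/(n₁−3) + 1/(n₂−3))`, for
pairs of correlations, with n = effective_df + 3 for volume correlations so
that n − 3 equals the effective df; and Fisher's exact test for constituent
count tables.  Joint (ecc, vcc) distributions of two conditions are compared
through Mahalanobis distances to the reference condition's bivariate mean
(unbiased covariance from the reference group only); the two distance
samples are compared with the Mann–Whitney U test — the comparison test is
not dictated by the source analysis and the rank test is consistent with the
rest of the ecc statistics.

## Salient regions

Voxels whose loadings fall strictly below the 1st or strictly above the
99th percentile (linear-interpolation definition, computed over masked
voxels only) are salient; clusters are connected components of each tail
under 18-connectivity (faces + edges, the common SPM convention;
configurable to 6 or 26) and clusters smaller than 32 voxels are dropped.
Each cluster reports its size, peak loading (largest |value|, ties to the
smallest linear index) and the peak position in MNI millimetres through the
image affine (0-based voxel indices, affine applied as stored).

## The synthetic-data generator

The generator is the package's test bed: it emulates the statistical
structure of a smoothed, spatially normalized event-related study so that
every downstream stage can be validated against known truth.

**Study conditions (defaults).** 10 subjects × 2 conditions
(placebo/verum) × 2 runs; 224 frames at TR 2 s; 6 s events with gaps drawn
uniformly from 8–12 s, packed from a 10 s offset until the scan ends (~27
events per run — the event count is a consequence of the timing parameters,
never a fixed input); grid 79 × 95 × 68 at 2 mm (full scale) with an
ellipsoidal gray-matter mask, and proportionally reduced grids for fast
runs; 8 mm FWHM smoothing for signal and noise alike.

**Signal.** Two unit-norm spatial networks are embedded: pattern I ("motor
control", three smoothed blobs in a sensorimotor-like location) and pattern
II ("distraction", posterior blobs carrying a negative copy of pattern I at
weight 0.4, which makes the two templates negatively volume-correlated as
the networks they emulate are).  Pattern I expresses along the unit-norm
modeled response; pattern II expresses along
`unit(−response + 2.5 · drift)` with a 0.012 Hz sinusoidal drift of
per-acquisition random phase — anticorrelated with the task but diluted, so
its |ecc| sits near 0.3–0.4 and the two time courses are separable by the
SVD (|corr| ≈ 0.37).

**Attentional states.** Each acquisition is *attentive* or *distracted*.
Attentive: pattern II is weak (singular value 0.35, below the noise edge —
it stays invisible).  Distracted (probability 0.35 under placebo, 0.15
under verum): pattern II expresses at 1.4 × the acquisition's pattern-I
gain.  This is what makes the distraction network surface irregularly and
more often under placebo — the condition effect the analysis is built to
detect — while keeping the within-acquisition gain ratio far from 1, where
SVD mixing would make classifications ambiguous.

**Gains and noise.** Pattern-I gains are 1.0 (placebo) and 1.3 (verum) —
the 30% verum advantage is the injected effect for the ecc comparison.  One
shared lognormal factor per acquisition (CV 0.15) scales both gains,
emulating between-subject/run expression variability without perturbing the
gain ratio.  Noise is AR(1) in time (coefficient 0.3), spatially smoothed
with the analysis FWHM, standardised to a sigma chosen by a one-realisation
calibration so that the placebo pattern-I singular value equals the top
singular value of the pure-noise residual matrix — component SNR ≈ 1, the
regime in which recovery is informative rather than trivial.  All
randomness descends from one master seed through the documented rule
`SeedSequence([master_seed, subject_index, condition_index, run_index])`.

**What the generator does not emulate.** Motion, physiological confounds,
slice-timing structure, field inhomogeneity, non-Gaussian noise, HRF
variability across regions or subjects, more than two networks, and any
k-space physics.  Passing tests therefore demonstrate that the analysis
recovers the modeled statistical structure at realistic SNR — not that it
is robust to every artefact of real acquisitions.

## Validation problem sizes

Chosen to exercise the claims at meaningful scale while keeping a full run
of the suite in the minutes range:

* **Analytic thresholds** — closed form, no simulation.
* **Type-I error** — 500 pure-noise 64-frame × 400-voxel acquisitions; the
  family-wise false-positive count is compared with α·500 plus three
  binomial standard deviations.
* **Parameter recovery** — the default study (40 acquisitions) on the
  reduced 40 × 48 × 34 grid (~23k masked voxels), master seed 0, analysed
  end to end once per session: pattern I retained in ≥ 90% of acquisitions,
  every MCI correlates ≥ 0.7 with its ground-truth network, first and
  second MCIs anticorrelate, and the pattern-I mean expression coefficient's
  spectrum peaks at the design fundamental (≈ 1/16 Hz).
* **Condition-effect power** — 50 replicate default studies on a
  16 × 19 × 14 grid; the Mann–Whitney comparison of pattern-I eccs must
  reach p < .05 in ≥ 80% of them.
* **Null vcc calibration** — 30 smoothed-noise images on a 30 × 36 × 26
  grid at 6 mm FWHM; implied effective df within a factor of two of the
  resel count.

## Numerical choices and degenerate inputs

* Periodogram normalisation `power = c_k|X_k|²/n` (one-sided, c = 2 except
  DC/Nyquist) makes the Parseval identity `sum(power) = n · var` exact; a
  constant series yields zero power rather than an error.
* A constant image has no percentile tails; thresholding returns empty maps.
* Zero-variance eigenvariates yield an undefined ecc (NaN) and are flagged
  not significant rather than raising.
* Mahalanobis analysis refuses singular reference covariances (condition
  number > 1e12) with advice to regularise.
* Mann–Whitney switches from exact enumeration to the normal approximation
  above group size 12.
* Classification tie-breaks (equal |vcc| within a cell) go to the smaller
  component index, making ledgers byte-reproducible.

## Known limitations

* The effective-df default (1660) is calibrated to the emulated study's
  geometry; other masks/smoothings should use `calibrate_null_vcc`.
* Rule 4 (cross-acquisition inconsistency) and the ambiguity margin are
  explicit operationalisations of loosely specified bookkeeping; both are
  configurable and flagged per component.
* The second-level control inherits the double-centering caveat above:
  its leading component is a scatter direction, and with homogeneous inputs
  it is not the mean pattern.
* The generator's two-network, two-state world is deliberately minimal;
  effect sizes measured on it do not transfer to real cohorts.
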