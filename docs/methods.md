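# Methods

This note documents the models, procedures, parameter choices and known
limitations of the `neuroage` package in one place.

## The estimation problem

Given a skull-stripped, intensity-normalized 3D T1-weighted volume, the
network regresses a single scalar — the brain age, in years. The brain
age difference (BAD) is the predicted brain age minus the chronological
age. Age-regression models systematically pull predictions toward the
training mean (overestimating young brains, underestimating old ones),
so raw outputs are corrected by modeling BAD as a linear function of
chronological age, `BAD = α·age + β`, fitted by ordinary least squares on
validation data and subtracted at inference. The final prediction is the
median over an ensemble of five identically configured, independently
initialized models; the sample variance of the corrected member outputs
is reported per scan as an agreement diagnostic.

## Synthetic phantoms

The phantom is a concentric-ellipsoid brain: a gray-matter (GM) ribbon
around a white-matter (WM) compartment containing a CSF-filled
ventricular ellipsoid, on an exactly-zero background (the z-scoring
contract depends on background zero). T1w-like contrast is used
(WM 1.0 > GM 0.7 > CSF 0.35, arbitrary units). Age enters linearly:

* ventricle radius `r(age) = r0 + g·age` (default `r0 = 0.07·min(dims)`
  voxels, `g = 0.0012·min(dims)` voxels/year, anisotropy (1.0, 1.3, 0.9)),
* GM ribbon thickness `t(age) = t0 − s·age` (default `t0 = 4` voxels,
  `s = 0.02` voxels/year),
* GM intensity rises by 8e-4 per year (gray/white contrast narrowing).

No quantitative human atrophy rates are claimed; the rates are free
parameters chosen once so that, across the supported age range 5–95
years, the geometry stays valid and the encoded signal is strong enough
for both a linear readout (two hand-computed features give R² > 0.9 at
zero noise) and a small CNN to recover age. Gaussian noise (sd 0.03 of
the WM intensity by default) is added inside the brain mask only; sites
act as pure multiplicative gains; sex is metadata with no structural
effect. All randomness descends from a single integer seed, with
per-subject streams derived from (seed, subject index), so every
generator is bit-reproducible.

WM lesions are hypointense spheres placed entirely inside WM (centers
constrained by a distance transform); the lesion-filled twin restores
the mean WM intensity inside the lesion mask and is identical to the
lesioned image elsewhere, emulating lesion filling before morphometry.

The longitudinal MS generator embeds, per subject, a true annual
brain-age change rate (default mean 1.15 years/year, between-subject sd
0.7, plus 0.34 for subjects flagged as worsening) so the analysis stage
can be validated by parameter recovery. The follow-up structural age is
exactly `baseline + rate × interval`; observed brain ages add Gaussian
prediction noise (sd 0.5 years). Baseline BAD is drawn at mean 4.2, sd
6.5 years; visit intervals are uniform on 1.4–4.3 years; these scales
mirror published MS cohorts. Clinical visits are constructed so that
worsening subjects cross exactly one randomly chosen threshold of the
disability-worsening rule and stable subjects stay strictly below all of
them (timed-test changes within −10%…+15%, EDSS steps below the branch
threshold).

What the phantoms do *not* emulate: anatomical detail (gyri, deep gray
matter, asymmetries), MR physics (no k-space acquisition, no real bias
fields or partial-volume mixing beyond voxelization), or multi-contrast
imaging. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it recovers a monotone structural age
signal — not that the network would reach any particular accuracy on
real MRI.

## Preprocessing

Fixed conventions: 0-based voxel indices, axis order (sagittal, coronal,
axial) matching the (160, 192, 160) network input, trilinear intensity
resampling, population (divide-by-N) standard deviation in z-scoring.
The canonical chain is strip → bias removal → rigid align → z-score →
crop/pad; the composition always yields the exact target dimensions,
zero background and finite values.

Skull stripping, N4 bias correction and rigid registration are in
practice performed by dedicated external tools. The module fixes their
contracts and ships internal fallbacks so the package runs with no
binaries installed; an `external_hook` registration mode accepts a
user-supplied callable at the same contract.

* **Bias removal fallback**: iteratively (5 rounds) fits a polynomial of
  total degree `order` (default 2) to the log-intensities of voxels
  within ±20% of the dominant-tissue intensity mode, divides the fitted
  field out, and restores the original nonzero-voxel mean. The
  mode-centered band keeps the fit on one tissue class so anatomy is not
  mistaken for field; `order=0` degenerates to the identity.
* **Rigid alignment fallback**: matches intensity centers of mass
  (translation) and principal axes of the second intensity moments
  (rotation; per-axis signs resolved toward the smallest rotation, with
  a determinant check), then resamples onto the template grid. On
  phantoms this recovers translations within 1 voxel and rotations
  within 1.5° of truth; it is not a substitute registration for real
  brains with complex anatomy.
* **Crop/pad** centers the *foreground bounding box* (not the grid
  center) in the target volume, padding with zeros and center-cropping
  oversize axes; foreground is conserved whenever the bounding box fits.
* **Z-scoring** uses only nonzero voxels, leaves zero voxels exactly
  zero, and raises on constant foreground. It is idempotent up to the
  measure-zero case of a voxel landing exactly on the mean.

7T sub-millimeter inputs are assumed resampled onto the 1 mm template
grid by the alignment step; the fixed input size means the pipeline does
not exploit native sub-millimeter resolution.

## Augmentation

Ten transforms, each gated by an independent Bernoulli(0.2) draw per
training iteration: rotations (each axis uniform within ±0.1 rad), small
affine (translation ±2 voxels, shear ±0.02), isotropic zoom (factor
uniform within [0.95, 1.05]), contrast scaling (0.75–1.25 about the
foreground mean), gamma (0.7–1.5 on the normalized intensity range, so
γ=1 is the identity), smooth multiplicative bias field (|log field| ≤
0.3), additive Gaussian noise (sd 0.01–0.1), patch swapping (8 cubes of
8³), motion (random phase perturbation of up to 10% of k-space lines
along one axis) and ghosting (periodic k-space amplitude modulation,
period 2–5, DC preserved).

Order is fixed as spatial → intensity → artifacts, so artifact patterns
are never re-interpolated. Sampling (`sample_plan`) and application
(`apply_plan`) are split, with sub-seeds for the stochastic transforms
stored in the plan: an iteration is fully reproducible from its plan.
Parameters are drawn whether or not a transform fires, so bound audits
(max |rotation| ≤ 0.1 rad, max |zoom−1| ≤ 5%) are exact statements about
the sampler. Every transform preserves the volume shape; motion and
ghosting preserve the background-zero property only approximately
(Gibbs ringing leaks small values into the background), which is
documented rather than asserted, and the additive-noise transform
deliberately covers the whole grid.

## Network and training

Blocks follow the depthwise(k³, per channel) → pointwise expansion
(×ratio, GELU) → pointwise compression pattern with a residual
connection; zeroing the compression weights makes a block the exact
identity, which is tested. Per-channel instance-style normalization
after the depthwise step keeps small-batch training stable. Four encoder
stages are the default, one block each, with stride-2 2³ convolutions
doubling channels between stages; kernel 3, expansion ratio 2 and the
channel/width defaults follow the small-model preset of the MedNeXt
family, since the exact trained widths of published models are not
recoverable from their descriptions. The head is global average pooling →
FC(hidden, default 64) + ReLU + dropout 0.2 → FC(1) + ReLU; both FC
layers use ReLU, with the accepted consequence that predictions are
nonnegative. The final bias is initialized at 50 years (mid-lifespan) so
the output unit starts active.

The layers are implemented directly in numpy (float32) with analytic
backward passes, verified against finite differences; eval-mode forward
passes are bit-deterministic. Training uses the squared-error loss,
batch size 4, AdamW (decoupled weight decay 1e-4 applied to convolution
and dense weights only) and a cosine learning-rate schedule; the default
learning rate is 1e-2, which suits the desk-scale networks this package
trains (a handful of thousands of parameters). Optimizer and schedule
are recorded in checkpoints; checkpoints round-trip bit-exactly.

The internal validation split is subject-level (repeat scans of a
subject never straddle the split) and stratified over 5-year age bins:
each occupied bin contributes at least one subject, targeting 5% of the
training set overall. The external validation set is every scan from one
held-out site. Selection keeps the epoch minimizing the average of the
two validation mean-squared errors, computed on raw outputs — the bias
correction is fitted only afterwards, per ensemble member, on the union
of the two validation sets (configurable; the union maximizes the fit's
stability). Ensemble members share splits and differ only in the seed
(seed + member index).

Desk-scale problem sizes used by the test suite: 32³ phantom grids, a
3-stage/4-channel network (≈ 3,900 parameters), 200 training phantoms
and 30 epochs for the end-to-end age-recovery check (a few minutes on
one CPU core); smaller 24³/16³ configurations for the unit tests. These
sizes are the package's validation conditions, not claims about
full-scale training.

## Statistics

Conventions fixed for reproducibility:

* **Mann-Whitney U**: `U1 = #{x<y} + 0.5·#ties`, reported under the
  min-U convention `min(U1, n1·n2 − U1)`; p-values from the normal
  approximation with tie correction and continuity correction;
  rank-biserial effect size `1 − 2U/(n1·n2)`.
* **Spearman**: Pearson correlation of midranks. Exact permutation
  p-values are enumerated for tie-free samples of n ≤ 8 (8! = 40,320
  pairings); larger or tied samples use the t approximation with n − 2
  degrees of freedom. Full enumeration at n = 9–10 would cost up to
  3.6 M permutations per call and is not worth it at this package's
  sample sizes.
* **Bootstrap**: percentile intervals (not BCa) over 1,000 resamples by
  default, deterministic given the seed.
* **BH-FDR**: step-up adjustment, capped at 1 (delegated to statsmodels).

Each statistic is validated against an independent brute-force oracle
(pair enumeration for U, the `1 − 6Σd²/(n(n²−1))` rank formula for
Spearman, a naive resampling loop for the bootstrap, hand-computed
step-up values for BH).

## MS analyses

Disability worsening is the standard composite rule: EDSS increase
≥ 1.0 when baseline EDSS < 6.0, or ≥ 0.5 when baseline EDSS ≥ 6.0, or a
≥ 20% increase (inclusive, consistent with the "≥" of the EDSS branches)
in T25FW or 9HPT time. All three components must be present — missing
data raises rather than being silently skipped, because a silent skip
would bias the worsening rate downward. The classifier is monotone:
worsening any component further never cancels a worsening verdict.

Disease-duration stratification splits at 6 years with the boundary
assigned to the longstanding group (the conventional "<6 vs ≥6"
reading). Annual brain-age change is `(brain_age₂ − brain_age₁) /
interval`, requiring a positive interval. The longitudinal report gives
the mean rate with IQR and a percentile-bootstrap 95% CI, a one-sample
t-test against 1 year/year (with the zero-spread degenerate case mapped
to a signed infinite t), and Mann-Whitney contrasts for worsening vs.
stable and early vs. longstanding subgroups; subgroup p-values are
jointly BH-adjusted. Group contrasts use Mann-Whitney throughout —
rate distributions are skewed, so a rank test is the safer default.

## Known limitations

* Phantom realism is intentionally minimal (see above); accuracy numbers
  on phantoms do not transfer to real MRI.
* The internal rigid alignment is moment-based and assumes a dominant,
  roughly ellipsoidal foreground; real brains need the external-tool
  hook.
* The numpy network is practical only at reduced resolutions and small
  channel counts; the full (160, 192, 160) input is supported by the
  implementation but is not a sensible CPU training size.
* The bias-field fallback assumes a dominant tissue class and smooth
  multiplicative fields of low polynomial order.
* Exact Spearman p-values are limited to n ≤ 8; ties always fall back to
  the t approximation.
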