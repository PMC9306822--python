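# Methods

`fetalvol` re-creates, on fully synthetic data, a measurement pipeline for
first-trimester fetal organ volumetry from 3D transvaginal ultrasound:
manual voxel segmentation with a spherical brush, an automated grayscale
border-refinement pass, mm³ volumetry, and the complete intra-/interobserver
reproducibility analysis (equality plots, ICC with 95% CI, within-subject
CV, Bland–Altman percentage limits of agreement, paired t-tests, a-priori
verdicts). Because no clinical datasets of this kind are publicly deposited,
every quantitative claim the package makes is validated against seeded
phantoms with closed-form ground truth.

## Data model

A `VoxelVolume` is a 3D grayscale grid (8-bit-equivalent intensities stored
as floats in [0, 255]) with per-axis voxel spacing in mm. Voxel indices are
0-based; the physical center of voxel *(i, j, k)* is
`origin + (index + 0.5) · spacing`, so `origin` is the corner of the first
voxel. NIfTI and NRRD headers address the center of the first voxel; readers
and writers shift by half a voxel to translate. The bit depth and intensity
calibration of clinical Cartesian volumes is not standardized; 8-bit
grayscale is assumed. A `SegmentMask` is a boolean grid aligned to a volume,
labelling one organ (heart, right/left lung, right/left kidney).

## Phantom generator

Each synthetic subject is a fetal-trunk-like volume containing five organs
as rotated ellipsoids, whose ground-truth volume is `(4/3)·π·a·b·c`. The
generator's defaults define the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| grid | 96³ voxels, 0.35 mm isotropic | 33.6 mm extent covers a late-first-trimester trunk; spacing inside the 0.2–0.5 mm range of clinical Cartesian volumes |
| background intensity | 60 | mid-dark abdominal echo texture |
| heart / lungs intensity | 180 / 170, 165 | high contrast (≥105 grayscale): these organs delineate well |
| kidneys intensity | 85 | contrast ~25: kidneys demarcate poorly from surrounding intestines and liver, reproducing the clinical difficulty ranking |
| speckle σ | 0.10 | multiplicative noise strong enough to stress the grayscale refinement without erasing contrast |
| organ volume ranges | heart 39–409, right lung 92–811, left lung 74–543, right kidney 28–245, left kidney 20–216 mm³ | the min–max spread of measured first-trimester organ volumes |

Per subject, one size factor *u* ~ Uniform(0, 1) places every organ volume
at `min + (0.04 + 0.92·u)·(max − min)` of its range, so organ volumes grow
together with fetal size and stay strictly inside the plausible ranges.
Subject seeds derive deterministically from the master seed
(`SeedSequence([seed, subject])`), so any subject is regenerable in
isolation.

Speckle is clamped multiplicative Gaussian noise,
`I → clip(I·(1 + σZ), 0, 255)` with one standard-normal draw per voxel — a
deliberate one-parameter simplification of Rayleigh envelope statistics. It
reproduces the property that noise amplitude scales with echo intensity,
which is what the grayscale refinement is sensitive to, but not the spatial
grain, point-spread blur, or depth-dependent attenuation of real speckle.
Optional shadow cones (apex, axis, half-angle, attenuation factor) emulate
acoustic shadowing; they default to off. An optional low-intensity
concentric heart core emulates the blood pool (off by default, so the
configured heart mean intensity is also its rendered mean).

Voxelization marks a voxel inside an organ iff its physical center lies in
the rotated ellipsoid. At σ = 0 and isotropic spacing ≤ (min semi-axis)/8
the voxelized volume agrees with the analytic volume to better than 2%
(tested); halving the spacing changes it by <1%.

## Simulated observers

Human segmentation variability is modelled in mask space, not by replaying
brush strokes: only the statistical structure of the produced masks matters
for reproducibility experiments. An `ObserverModel` has three error
components:

* **scale_bias** — multiplicative linear-size bias about the organ
  centroid; produced volumes scale with `scale_bias³`.
* **jitter_sd** — a smooth random radial boundary displacement, built from
  real spherical harmonics of degrees 1–3 with independent N(0, ·) seeded
  coefficients, normalized so every direction's marginal is exactly
  N(0, jitter_sd²) voxels. The field is exactly mean-zero over directions.
  A raw mean-zero displacement still inflates the expected volume by
  ≈ 3·jitter²/r² (outward lobes gain more voxels than inward lobes lose),
  so a constant radial offset is solved once per shape such that the
  expected included-voxel count equals the noiseless count — the expected
  count is a sum of normal CDFs over the mask's signed distances, and the
  offset is its unique root (Newton iteration). Simulated volumes are
  therefore unbiased under jitter alone (verified to within 1 SE at
  n = 200 on spheres and ellipsoids).
* **miss_rate** — probability of failing to produce a measurement,
  independent per subject/organ/repeat, emulating datasets in which an
  observer cannot perform a measurement without modelling image quality.

Membership is evaluated by thresholding a half-voxel signed Euclidean
distance map (interface at 0, adjacent voxel centers at ±0.5), interpolated
at rescaled coordinates when `scale_bias ≠ 1`; the largest face-connected
component is kept. Results are deterministic given
`(observer seed, subject, organ, repeat)`.

The default study uses two operators: observer 1 unbiased
(scale_bias 1.0), observer 2 systematically smaller (scale_bias 0.93),
both with jitter 1.25 voxels and 4% miss rate — qualitatively reproducing
good intraobserver agreement alongside consistent interobserver
differences, and 72–88% both-observer availability.

## Border refinement

After segmentation, let μ and s be the mean and *population* SD of volume
intensities over the pre-refinement mask. Every voxel whose Euclidean
center distance to the nearest border voxel (a mask voxel with ≥1
false/outside face-neighbor) is ≤ 5 voxels is relabelled: included iff
`|I − μ| ≤ k·s` (defaults k = 1, radius 5). μ and s are frozen for the pass;
voxels beyond the shell never change. Choices the one-sentence algorithm
statement leaves open, resolved here and recorded in `RefineStats`:

* the reference population for μ, s is the current segment (the only cohort
  the algorithm has);
* the rule applies symmetrically inside and outside the segment — the pass
  both trims and grows toward the anatomical boundary;
* distance is Euclidean in voxel units, measured to border-voxel centers;
* s = 0 degenerates to exact-intensity matching (a uniform volume grows by
  exactly the shell);
* a single pass by default (`iterations` re-estimates μ, s per pass);
* the largest face-connected component is kept afterwards
  (`keep_largest=False` disables).

The fast implementation (EDT-based, bounding-box cropped) is tested
voxel-for-voxel against an explicit triple-loop reference on random
fixtures.

**Measured behaviour.** For observers with a size bias the pass strongly
reduces volume error (scale_bias 0.90–1.10 on high-contrast organs: median
|error| ≈ 20–33% before, ≈ 7–11% after), and it removes interobserver bias
for high-contrast organs almost entirely. Its known limitation under
per-voxel speckle: ~32% of organ-intensity voxels lie outside μ ± 1s when
the mask is clean, so for an *already volume-unbiased* observer the pass
trims speckle tails and slightly worsens volume error (≈ 0.6–3% before vs
≈ 5% after on the default heart), and it systematically shrinks
low-contrast kidneys (≈ 17%), whose intensity distribution overlaps the
background. This is a property of the 1-SD rule itself, not of the
implementation.

## Volumetry and the study table

Volume = true-voxel count × voxel volume (spacing product), with no
partial-voxel correction — voxels are what the operator selected. The study
runner replays subject × organ × observer × repeat (2 × 2 design),
propagating missing measurements as flagged rows. Downstream analyses are
complete-case per organ and report n (%) available.

## Agreement statistics

Percentage differences use the Bland–Altman convention
`d = 100·(a − b)/((a + b)/2)`; limits of agreement are
`mean(d) ± 1.96·SD(d)` (sample SD, ddof 1). For the interobserver design
each observer's two repeats are averaged *before* differencing. The ICC is
the two-way absolute-agreement single-measurement form ICC(A,1), computed
from ANOVA mean squares, with the McGraw–Wong F-based 95% CI (a one-way
form is available via `icc_form="one_way"` for sensitivity; the form used
is recorded in every report). The within-subject CV uses the
root-mean-square method `100·sqrt(mean((d²/2)/m²))`; the SD-of-differences
variant is available via `cv_method="sd_diff"` since the clinical
convention is not uniquely determined. The paired t-test runs two-sided on
the percentage differences with n−1 df. Verdict flags implement the
a-priori thresholds: ICC > 0.90, CV < 10%, |mean difference| < 10%, and
both limits of agreement within 10 percentage points of the mean
difference. No multiple-testing adjustment is applied across organs.

Calibration checks (all recomputed by `scripts/acceptance.py`): the ICC
matches an explicit sums-of-squares oracle to 1e-10; its 95% CI covers a
true ICC of 0.8 in ≈95% of simulated two-way studies (n = 25, rater
variance 5% of total); ±1.96·SD limits contain ≈95% of Gaussian
differences at n = 10⁴; the paired t-test's type-I error is ≈5% for
identically-behaved simulated observers; and a 0.9 linear-size bias
(volume ratio 0.729) is recovered as a mean interobserver difference near
the theoretical `200·(1−0.729)/(1+0.729) = 31.35%` with essentially full
detection power at n = 25.

## Problem sizes and numerical choices

The replicate-study experiments (bias recovery over 200 studies, type-I
error over 1000) run on spherical truths with radii 6–10 voxels in small
padded boxes, drawn through the same segmentation sampler as the full
pipeline; observer statistics are scale invariant, so sphere size only
sets voxelization granularity. At these radii a 0.9-rescaled sphere
voxelizes to a volume ratio of 0.67–0.74 depending on radius, so the
recovered mean interobserver difference (~34.5%) sits a few points above
the continuum value 31.35% — a granularity effect, not an estimator bias.
The full end-to-end study uses 25 subjects at 96³. Distance comparisons use a 1e-9 absolute slack so that exact
integer distances (e.g. radius 5) are included; intensity thresholds use
exact `<=` so the s = 0 degenerate case matches exactly. Refinement and
sampling crop to padded bounding boxes; both are exact because every
border/true voxel lies inside the box. ICC CIs fall back to the limiting
F degrees of freedom (k−1) when the error mean square vanishes; degenerate
inputs (empty masks, zero variance, zero-SD differences, n < 3) raise
typed errors rather than returning numbers.

## Limitations

Phantoms are single ellipsoids with stationary uncorrelated speckle; no
point-spread function, attenuation with depth, refraction, fetal motion, or
anatomical shape complexity. Observer error is radial and smooth; real
operators make structured errors (e.g. truncating at the diaphragm).
Passing tests therefore demonstrate correctness of the algorithms and
calibration of the statistics under the stated noise model — not clinical
performance. Default contrasts are tuned only to make refinement behave
qualitatively as expected (lungs easy, kidneys hard) and are not claimed to
match clinical ultrasound intensity statistics.
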