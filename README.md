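# fetalvol

Synthetic-data reimplementation of a first-trimester fetal organ volumetry
pipeline: brush-based voxel segmentation of 3D transvaginal ultrasound,
automated grayscale border refinement, mm³ volumetry, and the full
intra-/interobserver reproducibility analysis.

## The problem

Volumes of the fetal heart, lungs and kidneys at 11–13 weeks of gestation
are measured by manually painting voxels in a 3D ultrasound dataset with a
spherical brush, post-processing the segment border by grayscale
similarity, and counting voxels. Before such measurements can support
research on early organ development, their reproducibility must be
established: do two repeats by one observer agree, and do two independent
observers agree? The clinical datasets behind published reproducibility
figures are not publicly available, so this package provides the entire
measurement chain **plus a seeded synthetic-data generator with closed-form
ground truth**, letting every algorithmic and statistical component be
validated end to end. It is aimed at researchers developing or stress-testing
volumetry and observer-agreement methodology.

## What is implemented

* **Phantoms** — fetal-trunk-like 96³ grayscale volumes (0.35 mm voxels)
  with five ellipsoidal organs of known volume V = (4/3)πabc, organ/background
  contrast, clamped multiplicative speckle I → clip(I(1+σZ), 0, 255), and
  optional acoustic shadow cones. Kidneys are rendered at low contrast
  (hard), heart and lungs at high contrast (easy).
* **Observers** — a spherical brush (`apply_brush`) and statistical observer
  models: linear-size bias β (volume scales with β³), a smooth mean-zero,
  volume-preserving radial boundary jitter built from spherical harmonics,
  and a per-measurement miss probability.
* **Refinement** — the border post-processing pass: with μ, s the mean and
  population SD of intensities over the segment, every voxel within a
  5-voxel Euclidean radius of the segment border is relabelled to
  `|I − μ| ≤ k·s` (default k = 1), single pass, frozen μ and s.
* **Volumetry** — volume = voxel count × spacing product; study runner for
  the subjects × organs × 2 observers × 2 repeats design with missing
  measurements kept as flagged rows.
* **Agreement** — Bland–Altman percentage differences
  d = 100(a−b)/((a+b)/2) with limits of agreement mean(d) ± 1.96·SD(d);
  two-way absolute-agreement single-measurement ICC(A,1) with McGraw–Wong
  95% CI; within-subject RMS coefficient of variation
  CV = 100·√(mean(d²ᵣₐw/2m²)); two-sided paired t-test on d; a-priori
  verdicts (ICC > 0.90, CV < 10%, |mean d| < 10%, LoA within ±10 points of
  mean d).

## Worked example

Run a complete simulated reproducibility study (25 subjects, two observers —
the second one segmenting 7% small in linear size — two repeats each,
refinement on):

```sh
fetalvol run-study --n-subjects 25 --seed 7 --out-dir out
```

which prints `500 measurement records -> out` and writes `measurements.csv`,
`descriptives.csv`, `availability.csv`, `agreement.csv/.json`, the phantom
truth table and a provenance record. The same study from Python:

```python
import fetalvol as fv

specs = fv.default_study_spec(n_subjects=25, seed=7)
observers = [
    fv.ObserverModel("obs1", scale_bias=1.00, jitter_sd=1.25, miss_rate=0.04),
    fv.ObserverModel("obs2", scale_bias=0.93, jitter_sd=1.25, miss_rate=0.04),
]
result = fv.run_study(specs, observers, fv.RefineParams(), seed=7)
print(fv.agreement_table(result.records).round(3).to_string())
```

Selected rows of the agreement table (seed 7):

```
    design        organ  n   icc  cv_pct  mean_diff_pct  loa_lower_pct  loa_upper_pct  p_value
intra:obs1        heart 23 1.000   1.488          0.252         -3.934          4.437    0.578
     inter        heart 22 0.996   2.509          2.683         -1.976          7.342    0.000
intra:obs1 kidney_right 23 0.952  13.751         -5.545        -42.899         31.808    0.177
     inter kidney_right 21 0.975   8.127          4.497        -16.746         25.739    0.072
     inter  kidney_left 23 0.831  14.718         13.186        -19.090         45.461    0.001
```

Reading it: intraobserver agreement is excellent for the high-contrast
heart (ICC 1.00, CV 1.5%) and markedly worse for the low-contrast kidneys
(CV ~14%, limits of agreement spanning ±37 points) — the deliberate
difficulty ranking of the phantom. The interobserver rows detect the
built-in size bias of observer 2 as consistent measurement differences
(paired-t p ≤ 0.001 for heart and left kidney) even though the border
refinement has pulled both observers' segmentations toward the true
grayscale boundary (mean interobserver difference ~2.7% for the heart
instead of the ~22% the raw 0.93³ volume bias would produce). Per-organ
availability (subjects where both observers produced both repeats) lands
at 84–92%.

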