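# Methods

## The conformal layer

The segmenter is treated as a collection of per-voxel binary classifiers
emitting a foreground probability `p_fg ∈ [0, 1]`. Nonconformity of a voxel
for candidate label `y ∈ {0, 1}` is `s(y) = 1 − p_y`, the canonical
model-agnostic score for probabilistic classifiers. Calibration scores are
partitioned by the *true* voxel label (Mondrian categories), which makes the
coverage guarantee hold per class and renders the extreme
background/foreground imbalance harmless for validity.

The p-value is the conservative smoothed rank
`p = (#{sᵢ ≥ s} + 1)/(n + 1)` with ties counted as ≥. This choice is
deterministic (no randomized smoothing) and valid for every calibration size
`n`; the price is a conservatism of order `1/(n + 1)`. A label enters a
voxel's prediction set iff `p > α`. The set is coded BG / FG / BOTH / EMPTY;
BOTH and EMPTY are pooled into a single "uncertain" flag for all downstream
masking, since a deployment would defer both cases to a reader.

Calibration voxels are subsampled uniformly without replacement to a
per-exam per-class cap (default 2000, seeded). A full exam holds ~10⁶
voxels, so the cap keeps calibration tractable while each exam contributes
equally per class. Calibration exams are never reused for evaluation.

Conformal prediction is pointwise, so the layer is applied voxel-wise on the
assembled 3D probability map; whether the underlying model worked per slice
or per volume is irrelevant to the scores.

**What the guarantee does and does not say.** Marginal per-class coverage
`≥ 1 − α` holds in expectation over the joint draw of calibration and test
data. Realized coverage on one finite cohort fluctuates around the nominal
level, and because voxels within an exam are strongly correlated (shared
anatomy, spatially correlated segmenter noise), the effective sample size of
that fluctuation is the number of *exams*, not voxels — empirically ±1–2 %
at 40 calibration exams, orders of magnitude wider than a binomial margin at
the pooled voxel count would suggest. Multi-cohort averages recover the
nominal level (verified by a Monte-Carlo property test).

## The phantom cohort

Each exam is generated i.i.d. from a `PhantomSpec` (so calibration and
evaluation splits are exchangeable by construction):

* **Shape** — an ellipsoid with per-exam semi-axes drawn uniformly
  (defaults: 12–20 mm in-plane, 10–16 mm through-plane), radially perturbed
  by a random real-spherical-harmonic field of orders 2–4 scaled to a peak
  amplitude of 8 % of the local radius. This breaks the pure-ellipsoid
  assumption behind the reference formula while keeping the geometry
  analytic.
* **Grid** — 96 × 96 × 16 voxels at 0.5 × 0.5 × 3.0 mm, the common resampling
  space used for axial T2w prostate MRI. The ~48 mm field of view means
  phantom volumes are ~6–30 mL, a scaled-down prostate; all acceptance
  properties are relative (coverage, directional effects), so absolute organ
  size does not enter them.
* **Emulated segmenter** — `p = logistic(β · d)` where `d` is the Euclidean
  signed distance (mm, positive inside) to the organ surface shifted
  outward by a bias `b`, plus additive Gaussian noise that is spatially
  correlated (white noise smoothed to a 4 mm correlation length, scaled to
  SD 0.15) and clipped to [0, 1]. Defaults: β = 2 /mm (a 10–90 % transition
  width of ≈ 2.2 mm, plausible for an ensemble-averaged model at the prostate
  boundary) and b = +1 mm, reproducing the over-segmentation behaviour
  reported for DL prostate models. Correlated rather than independent noise
  is deliberate: independent noise would average out at the first
  neighborhood scale and make the conformal task trivially easy.
* **Reference reading** — axis extents W, H, D of the continuous (unbiased)
  deformed surface, measured on a dense direction sampling like a caliper
  reading (exactly 2a, 2b, 2c when the deformation is zero), each multiplied
  by `1 + ε` with `ε ~ N(0, 0.05)` — manual ellipsoid measurements err
  proportionally — then `PV_ref = (π/6)·W·H·D`.

Every random draw flows from the supplied seeds (a `SeedSequence` spawn per
exam); no global RNG state is touched.

What the phantom does **not** emulate: MRI texture and appearance, multiple
organs, scanner/vendor effects, inter-exam heterogeneity of the segmenter's
bias (b is a single scalar, so every exam is over-segmented by the same
margin — see Limitations), and non-ellipsoidal pathology such as large
median lobes.

## Volumes and metrics

* `mask_volume` = voxel count × voxel volume / 1000 (mL).
* `ellipsoid_volume` uses π/6 (the PI-RADS 2.1 canonical constant) rather
  than the rounded 0.52; the difference is < 1 %.
* `rvd = (pv − pv_ref)/pv_ref`, positive = overestimation. Overestimation is
  not bounded above by +1 under this definition and is not clipped.
* Dice and ASD "with CP" exclude uncertain voxels from **both** prediction
  and reference before computation: the evaluation is restricted to voxels
  the system commits on, matching the deployment framing in which withheld
  pixels are a reader's responsibility. (Treating uncertain as background is
  the obvious alternative; it conflates abstention with a negative call and
  cannot raise Dice, so it is not the default.)
* ASD uses face-adjacent (6-connectivity) boundary voxels and
  center-to-center physical distances in mm; all distances from both
  boundaries are averaged together. An empty mask after exclusion makes the
  metric undefined — recorded as missing, never 0, since 0 would reward
  empty predictions.
* ECE uses 10 equal-width bins on `p_fg` (configurable). ECE and Brier "with
  CP" use the original probabilities on the retained voxels only — the
  conformal layer never alters probabilities, only the commitment set.
  Both are reported as fractions in [0, 1].

## Agreement statistics

ICC is ICC(2,1) — two-way random effects, absolute agreement, single
measurement — the standard model for comparing single readings from two
methods; the 95 % CI is F-based. Reliability categories: poor < 0.50 ≤
moderate ≤ 0.75 < good ≤ 0.90 < excellent (boundary values resolved to the
lower category, so 0.75 is "moderate"). Bland–Altman uses
`method − reference` differences (positive bias = overestimation), sample
SD, and 1.96 limits. Spearman CIs come from a seeded nonparametric pairs
bootstrap (percentile, default 2000 resamples). Paired comparisons are
gated by Shapiro–Wilk on the differences at 0.05: normal → paired t-test,
otherwise Wilcoxon signed-rank with zeros dropped and average ranks.
All-zero differences short-circuit to a degenerate result with p = 1.
No multiple-testing correction is applied across metric comparisons; the
report says so in a footer note.

## Imaging conventions

Voxel indices are 0-based; physical position = origin + index × spacing;
array axes are (x, y, z) with z the slice axis. Intensities resample with
third-order splines, masks with linear interpolation of the 0/1 field
followed by thresholding at 0.5 (ties → foreground). Resampled intensities
are clamped to the input range to suppress spline overshoot, which keeps
resampled probability maps inside [0, 1]. Intensity normalization is a
per-volume z-score with population SD; by default it runs after resampling,
but the order is configurable. NIfTI masks are written as uint8,
probabilities as float32, region maps as uint8 with the code legend in the
header description.

## Problem sizes

The cohort-scale experiments run 40 calibration + 200 evaluation exams on
96 × 96 × 16 grids (the scale at which the validity and directional-effect
properties are checked); unit and property tests use 48 × 48 × 12 grids with
proportionally smaller organs. The exchangeability and coverage Monte-Carlo
checks use reduced replicate counts at the small scale.

## Known limitations

* With a homogeneous segmenter bias, conformal masking corrects the *mean*
  volume error but cannot narrow the Bland–Altman limits of agreement
  against the reference: there is no exam-level bias heterogeneity to
  remove, and the certain-foreground isoprobability surface (~p ≈ 0.88 at
  α = 0.15) lies on a flatter part of the logistic than the 0.5 threshold,
  so its noise-induced wobble — hence the conformal volume's variance — is
  larger. Narrower limits require per-exam bias variability of the kind real
  DL models exhibit.
* Single-cohort empirical coverage is an exam-level statistic; see the
  conformal section. Guarantees are marginal, not per-exam or per-region.
* The phantom's scaled-down geometry inflates relative volume errors for a
  given boundary offset (+1 mm on a ~16 mm radius is ~+18 % RVD); directional
  conclusions transfer, absolute RVD magnitudes do not.
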