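# Methods

`plusquant` quantifies the two vascular signs that define Plus disease in
retinopathy of prematurity (ROP) — abnormal tortuosity and dilation of the
posterior-pole vessels — plus vessel density, from a binary vessel mask and
an optic-disc location, and classifies images as Plus vs non-Plus. This note
documents the model, the estimators, the tunable parameters, the synthetic
data the tests run on, and the limits of what those tests show.

## Tortuosity model

Each vessel segment is represented by a parametric cubic spline
γ(t) = (x(t), y(t)), with t the cumulative chord length of the control
points. Curvature is the standard planar expression

    κ(t) = |x′(t) y″(t) − y′(t) x″(t)| / (x′(t)² + y′(t)²)^(3/2)

and the tortuosity of a segment is the squared-derivative-curvature index

    T = ∫ (dκ/ds)² ds / L_c ,     L_c = ∫ √(x′² + y′²) dt ,

with s arc length. T is zero for straight segments *and* for circular arcs
(κ constant), and it grows with both the amount and the sharpness of
direction change per unit length — which is what distinguishes the corkscrew
vessels of Plus disease from a smoothly curved but healthy arcade. Units are
px⁻⁴; values are resolution-dependent, which is acceptable within a cohort
imaged at one resolution because all features are standardized before
classification.

### From pixels to a smooth curve

1. **Thinning.** The mask is reduced to a one-pixel-wide, topology-preserving
   skeleton (`skimage.morphology.skeletonize`).
2. **Spur pruning.** Free-end branches shorter than
   `skeleton.min_branch_len` (default 10 px) that hang off a junction are
   deleted, repeatedly, until stable. Spurs are boundary-noise artifacts;
   pruning leaves genuine branches intact.
3. **Segment splitting.** Junction pixels (≥ 3 skeleton neighbors, after
   removing redundant diagonal links in 2×2 thinning artifacts) are removed
   and each remaining branch is traced into an ordered path, starting from
   its lexicographically smallest endpoint for reproducibility. Paths
   shorter than `skeleton.min_segment_len` (default 30 px) are discarded:
   curvature derivatives are meaningless on shorter runs.
4. **Down-sampling.** Control points are taken at uniform chord-length
   intervals of `spline.spacing_px` (default 15 px; symmetric targets, so a
   reversed path yields the same estimate). Interpolating through every
   skeleton pixel would chase quantization noise rather than vessel
   geometry.
5. **Subpixel refinement** (`spline.refine_subpixel`, default on). Integer
   skeleton pixels carry ±0.5 px quantization error, which the
   (κ′)²-integral amplifies badly. The true centerline of a locally
   constant-width vessel maximizes the distance to the vessel border, so
   each control point is slid along its local normal onto the
   parabola-fitted crest of the Gaussian-smoothed (σ = 1.5 px) distance
   transform of the mask. Two passes; residual error is of order 0.1 px.
6. **Spline fit.** Interpolating parametric cubic with not-a-knot end
   conditions. Natural ends would clamp κ to zero at the segment tips and
   manufacture a spurious curvature-derivative spike there (measured: it
   alone raises the T of a perfect circular arc to ~4 × 10⁻⁸ px⁻⁴, versus
   ~4 × 10⁻¹² with not-a-knot). An optional penalized fit
   (`spline.smoothing` > 0) is available but off by default.

### Numerical evaluation

κ is evaluated analytically from the spline derivatives on a uniform
parameter grid (`curvature.n_samples`, default 200), re-expressed on a
uniform arc-length grid, and differentiated with a Savitzky–Golay filter of
order `curvature.savgol_order` (default 5) and arc-length support
`curvature.savgol_window_px` (default 50 px, capped at a third of the
segment). The filter is a local least-squares derivative: it suppresses the
residual pixelation ripple at the control-point scale while the quintic fit
passes vessel winding at the clinically relevant ~100 px wavelengths. Set
the window to 0 for plain centered differences (appropriate on noise-free
analytic control points). L_c uses composite-Simpson quadrature of the
parametric speed; T uses trapezoidal integration over arc length.

These choices were fixed by measuring against analytic phantoms: with them,
mean curvature of rasterized circular arcs (R = 50–100 px) is recovered
within ~1%, rasterized-sinusoid T agrees with dense quadrature on the
generating curve within 8% for amplitudes 5–20 px at a 120 px wavelength,
and T is strictly monotone over the amplitude ladder {2, 5, 10, 15, 20} px.
At amplitude 2 px the analytic T (~4 × 10⁻⁸ px⁻⁴) sits below the pixelation
noise floor and only the ordering, not the value, is reliable.

## Image-level features

* **F1** — mean T of the 5 most tortuous segments, entire image (all
  segments, with a warning, if fewer than 5; ties broken by segment id).
* **F2** — mean T of segments assigned to the 5DD zone.
* **F3** — mean of the top 1% (at least one) of all curvature samples pooled
  across the image's segments. Pooling is per image, not per segment.
* **F4** — largest mean segment diameter in the 5DD zone (the venule is
  assumed widest).
* **F5** — vessel density: vessel pixels divided by the non-vessel remainder
  of the vascularized region, where the vascularized region is one
  morphological dilation of the mask with a disc footprint of radius
  `density.dilation_radius_px` (default 25 px ≈ one disc radius at this
  scale; the choice is a convention, and density comparisons are only
  meaningful at a fixed radius).

The **5DD zone** is the annulus from the optic-disc border to five disc
diameters beyond it (disc interior excluded); a segment belongs to it when
at least `zone.membership_threshold` (default 50%) of its centerline pixels
fall inside. Images in which no segment reaches the zone get missing F2/F4
and are excluded from classification with a logged reason.

**Caliber.** At a seeded random third (`caliber.fraction`) of a segment's
centerline pixels, the local width is 2·d − 1 px, where d is the Euclidean
distance-transform value (centerline pixel center to nearest background
pixel center). The −1 accounts for the half-pixel border offset on each
side: a ribbon rasterized w pixels wide reports exactly w when axis-aligned
and within ~1 px at any orientation. `caliber.halfwidth_convention` instead
reports d itself — the literal center-to-border distance — which halves all
calibers uniformly (standardization absorbs it). Samples whose
distance-transform value could be clipped by the image border, or within
`skeleton.min_branch_len` of a junction (where crossing vessels inflate the
width), are dropped.

Five auxiliary features are also computed (arc-over-chord ratio mean, mean
and median segment T, image mean diameter, segment count). They are
plausible companions to F1–F5, not claimed to match any particular
previously used set; the NCA step decides whether they contribute.

## Classification

Pipeline per training fold (no test-fold leakage; `cv.legacy_leaky`
reproduces the variant fitted on all rows):

1. **Standardize** each feature to zero mean, unit sample variance.
2. **NCA feature selection** — the feature-weighting variant of neighborhood
   component analysis: nonnegative per-feature weights w scale an L1
   distance d_ij = Σ w_l² |x_il − x_jl|; a leave-one-out stochastic-neighbor
   objective (softmax over −d_ij) minus an ℓ₂ penalty
   (`nca.regularization`, default 1.0) is maximized by adaptive-step
   gradient ascent (tolerance 10⁻⁶, ≤ 500 iterations). The top
   `nca.k` = 5 features by weight are kept (ties by feature order). This is
   written in-package: library NCA implementations learn a full linear
   transform, not per-feature weights.
3. **PCA** to the first three components (deterministic sign: each loading's
   largest-magnitude element is positive).
4. **RBF-kernel SVM**, regularization C = 1, `svm.gamma` defaulting to
   1/(n_components × variance of the projected training data).

Performance is summarized by repeated stratified tenfold cross-validation
(`cv.folds` = 10, `cv.repeats` = 10): predictions are pooled per repeat into
one confusion matrix; accuracy, sensitivity, specificity, PPV and NPV
(Plus = positive) are reported as mean ± sample SD over repeats. Group
differences per feature use a two-sided rank-sum test (the feature
distributions are skewed with outliers) with Bonferroni correction over the
number of features tested.

## Rater agreement

Cohen's kappa and absolute agreement are computed from the 2×2 contingency
of paired binary labels; kappa is reported missing (never 0) when a rater is
constant. The reference standard is the per-image majority over an odd
number of raters — no tie rule is defined, so an even rater count is an
error. Which labeling session feeds the inter-rater and vs-reference tables
is an explicit argument everywhere (labels are collected twice and the
choice is a study decision, not a package default). Summary mean/SD of
agreement percentages use the sample (n−1) standard deviation.

## Synthetic phantoms

The generator exists so that every stage has analytic ground truth.

* `rasterize_vessel` draws a constant-width ribbon (pixels within w/2 of the
  densely sampled curve) around a line, circular arc, sinusoid, or
  two-harmonic wiggle. The truth record (κ summary, arc length, T) comes
  from dense quadrature on the *analytic* derivatives — never from the
  raster or the spline pipeline — so it is an independent oracle.
* `make_cohort` emulates a two-class posterior-pole cohort: per image, 6–12
  sinusoidal branches radiate outward from the optic-disc border; one branch
  is the venule (widest). The default class conditions are a well-separated
  ("easy") regime — sinusoid amplitude 15 ± 2 vs 4 ± 1 px, venule width
  19 ± 2 vs 13 ± 2 px, branch count 11 ± 1 vs 7 ± 1 — i.e., frank Plus
  disease against quiet posterior poles. Default canvas 1200 × 1600 px
  (disc diameter ≈ 8% of the short side); the test suite generates at 512²
  with a 40 px disc, which scales the geometry proportionally. Branch
  wavelengths are drawn at 100 ± 10 px.
* `make_rater_table` flips the reference label independently with a
  per-rater error probability (< 0.5), twice per rater, emulating two
  grading sessions.

What the phantoms deliberately lack: intensity and illumination structure,
segmentation errors (vessel segmentation is upstream of this package),
width taper along vessels, artery/vein distinction, and intermediate
("pre-Plus") severity. Passing tests therefore demonstrate that the
estimators recover known geometry and that the pipeline separates
well-separated classes without leakage — they do not certify clinical
accuracy on fundus photographs, where segmentation quality dominates.

On the seeded 40-image easy cohort the suite checks: repeated tenfold CV
accuracy ≥ 0.95 with SD ≤ 0.03, permuted-label accuracy within 0.5 ± 0.15,
Spearman rank recovery of generating parameters (max branch width vs F4
≥ 0.9; branch count vs F5 ≥ 0.8; top-5 analytic branch tortuosity vs F1
≥ 0.8 — F1 is a top-of-distribution statistic, so it is matched to the
top-5 generating summary rather than the per-image mean amplitude, whose
rank correlation is ceiling-limited near 0.75 by the two-group structure),
and exact F1 class separation.

## Degenerate inputs and tie-breaks

Empty masks give empty skeletons; images with no usable segment fail
feature extraction with a logged reason (the CLI continues with the rest of
the directory). Zero-speed spline samples are dropped from curvature
profiles with a warning. Ties in the "5 most tortuous" ranking break by
ascending segment id; path tracing starts at the lexicographically smallest
endpoint; junction detection resolves 2×2 thinning blocks by dropping
diagonal links that shortcut an orthogonal pair. Every random step (caliber
sampling, cohort generation, rater flips, CV shuffling, NCA initialization)
is seeded, and the CLI echoes the tool version, the full configuration and
its hash into every output artifact.

## Known limitations

* T is resolution-dependent by construction; compare only within a cohort
  at one scale (standardization handles the classifier's needs).
* Tortuosity of very gently winding vessels (amplitude ≲ 2 px) is below the
  pixelation noise floor; ordering is preserved but absolute values are not
  trustworthy there.
* Caliber assumes locally constant width; junction-adjacent samples are
  excluded rather than modeled.
* The 5DD zone is a planar annulus in image coordinates; no account is
  taken of retinal curvature or camera projection.
* The headline clinical cross-validation figure of the original 76-image
  study is not reproducible here: that dataset is available only on request,
  so the end-to-end classification checks run on synthetic cohorts.
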