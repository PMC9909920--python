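# Methods

`gliaquant` quantifies demyelination/remyelination readouts of the
cuprizone mouse model from two data streams — DAB/hematoxylin brightfield
histology and small-animal MRI — and runs the group statistics such studies
report. Because studies of this kind publish group summaries rather than
raw images, every stage is validated against a synthetic ground-truth
generator that is part of the package, not a test fixture.

## Color model and stain separation

Brightfield absorption is multiplicative, so images are analyzed in
optical density, `OD = -log10(I / I0)` per RGB channel with white point
`I0` (default 255 per channel; the per-channel 99th percentile of the
image is available as an estimator when the background is not saturated).
Intensities are clipped to `[1, I0]` before the log so OD is finite and
nonnegative; rendering saturates at the OD that maps to intensity 1, never
0, so the transform round-trips.

A pixel's OD vector is modeled as a nonnegative combination of unit-norm
per-stain color vectors. The default basis is the standard published
H-DAB basis — hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈ (0.269, 0.568,
0.778), residual = their normalized cross product — and is
user-overridable (3×3 CSV); automatic basis estimation (Macenko/NMF) is
deliberately out of scope. Unmixing is the per-pixel 3×3 linear solve,
with negative concentrations clipped at zero by default (they can only
arise from noise). On noise-free composites the reconstruction error is
at machine precision, which the synthetic generator exploits by
compositing scenes in OD space with the same basis.

## Microglia morphometry

The pipeline reproduces a soma/process morphometry procedure for
Iba1-like DAB staining:

1. **Tissue mask** — grayscale threshold against the white background
   (default: mean intensity < 245), then closing, hole filling, opening
   (disk radius 3) and removal of components < 500 px.
2. **Adaptive dark-region statistic** — the mean DAB concentration of the
   darkest `dark_quantile` fraction of tissue pixels (default 0.3%),
   i.e. of soma-like regions. Both segmentation thresholds scale from
   this statistic, which makes the pipeline invariant to global staining
   intensity: doubling the DAB signal, or brightening the whole image,
   changes neither soma count nor masks. The quantile must be small
   enough that the dark set is dominated by soma pixels; 0.3% of a
   512×512 field corresponds to roughly 700 px, below the soma area of
   the sparsest scenes we target (≥ 10 cells of ~100 px²).
3. **Soma** — threshold = statistic × `soma_factor` (default 0.65),
   binarize within tissue, fill holes, keep components with area in
   [30, 1500] px². Per-soma centroid, area, and Crofton perimeter
   (4 directions) are recorded; the Crofton estimator keeps the form
   factor `4πA/P²` of a rasterized disk within [0.9, 1.05].
4. **Processes** — white top-hat with a disk of radius 2 (larger than the
   ~1 px process half-width, smaller than soma), threshold = statistic ×
   `process_factor` (default 0.3), size filter ≥ 5 px (8-connected), then
   subtraction of the soma dilated by 2 px: the top hat also responds at
   the soma rim, and subtracting a slightly dilated soma removes that rim
   ring without measurably shortening processes.
5. **Skeleton and length** — `skimage` thinning to a 1-px skeleton;
   length counts each 8-adjacency link once: 1 per axial step, √2 per
   diagonal step. A horizontal 20-px line measures 19; a 20-px diagonal
   19√2.
6. **Proximal/distal partition** — the soma dilated `n_dilations` times
   (default 3, 3×3 element) is the marker region; a circle of radius
   `circle_radius_factor` × median soma equivalent radius (default 4×)
   around each soma centre bounds the proximal zone. Skeleton components
   touching a marker are kept (background fragments are ignored); their
   pixels inside a circle are proximal, assigned to the nearest soma
   centre where circles overlap (ties to the lower cell id); the
   remainder of those components outside the circles is distal,
   attributed to the cell owning most of the component's proximal pixels.
7. **Per-cell measures** — soma area (px², µm² via `pixel_size_um`,
   default 0.47 µm at a 20×-like scale), form factor, proximal/distal
   skeleton lengths, and background-corrected optical densities: soma OD
   and "visible microglia" OD (soma + proximal processes) minus the
   median DAB OD in an annulus (width 5 px) around the cell's circle,
   excluding all visible-microglia pixels; an empty annulus falls back to
   the tissue-wide median and flags the record.
8. **ROI readouts** — microglia numbers (soma centroids in the ROI per
   mm² of ROI) and microglia activation (soma + proximal process area
   over distal process area). A zero denominator sets an explicit
   undefined flag instead of raising or returning infinity. The
   denominator can optionally be every non-soma-associated process pixel
   including background fragments (`activation_denominator =
   "all_nonsoma"`); the default excludes fragments that touch no soma,
   matching the reconstruction-from-proximal definition of distal
   processes.

The number of soma dilations, the circle radius factor, both threshold
factors and the size filters are deliberate free parameters of this kind
of procedure; the defaults above were chosen once against the generator's
geometry and are exposed in `MorphometryConfig` (YAML-loadable).

## Stain quantification

Area-% readouts (GFAP, dMBP, SMI312, LAMP-1, TMEM119, GST-π style)
threshold the deconvolved stain channel over an ROI — either a fixed OD
cut per stain (preferred, stored in config) or Otsu on the ROI as a
fallback — and report the stained fraction in percent. Myelin stains
(LFB style) use integrated optical density, the plain sum of per-pixel OD
over the ROI. Group-reference normalization divides a measure by the
mean of a designated reference group (e.g. wild-type on control food),
optionally ×100. All table operations are fenced by `study_id`: each
study arm carries its own wild-type reference, and any attempt to pool
groups across studies raises.

## MRI quantification

* **MTR** — `MTR = (S0 − SMTR) / S0` per pixel from the acquisitions
  without/with magnetization-transfer saturation. Pixels with S0 at or
  below a noise floor (default 3× the SD of a corner background patch)
  are marked invalid and excluded from ROI means rather than zeroed.
  Negative MTR values are retained, not clipped — clipping would bias ROI
  means at low SNR.
* **T2** — mono-exponential fit `S(TE) = S0·exp(−TE/T2)` to the ROI-mean
  signal across echoes (the simulated schedule is 16 echoes spaced 11 ms,
  TE 11–176 ms, in-plane pixel size 0.094 mm), initialized by log-linear
  regression and refined by nonlinear least squares; a non-decaying
  series returns a failed-convergence flag. No constant-offset term by
  default: the model is deliberately mono-exponential, and the fit is
  performed on ROI means rather than pixelwise (pixelwise fitting is
  possible by calling the fitter per pixel but is not the primary path).
* **Relative signal** — per-timepoint ROI means divided by the baseline
  timepoint; scale-invariant by construction.

## Statistics

* **Holm–Šídák** step-down adjustment: for raw p sorted ascending,
  `adj(i) = 1 − (1 − p(i))^(m−i+1)`, made monotone by a running maximum
  and capped at 1 (delegated to `statsmodels.multipletests`, verified
  against the closed formula in the tests). Stars follow the convention
  *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001.
* **One-way ANOVA** with pairwise contrasts using the pooled mean-square
  error (df = N − k); the adjustment family is exactly the requested set
  of comparisons. A Welch option is not provided; pooled error mirrors
  classic multiple-comparison semantics.
* **Two-way ANOVA** (type-II table via `statsmodels` OLS) with cellwise
  contrasts on the residual mean square; the default family compares
  genotypes within each timepoint.
* **Longitudinal ("ANOVA with random effects")** — a linear mixed model
  with a per-animal random intercept fit by REML (`statsmodels MixedLM`),
  fixed effects group, time and group×time. Denominator degrees of
  freedom use the containment heuristic: between-animal df
  (animals − groups) for the group effect and group contrasts,
  within-animal residual df for time and interaction. This is a surrogate
  for legacy mixed-ANOVA software whose exact covariance structure and df
  method are not specified; in the zero-between-animal-variance limit its
  fixed effects coincide with the two-way OLS fit to ~1e−15. Results are
  conventionally reported as per-timepoint group comparisons, so
  `detects_group_time_effect` counts either a significant interaction or
  any significant adjusted post-baseline contrast.
* **Assays** — 2^−ΔΔCt relative expression (ΔCt against a reference gene,
  ΔΔCt against the control-group mean ΔCt, so the control geometric mean
  fold is 1); ELISA standard curves as four-parameter logistic fits with
  a log-log linear fallback, inverse prediction refusing to extrapolate
  outside the standards' fitted response range; trapezoidal AUC of
  time courses; percent-of-reference normalization (reference mean maps
  to 100).

## Synthetic data: what it emulates and what it does not

The IHC generator composites, in OD space, a smooth random tissue blob
(hematoxylin OD 0.25), disk somas (radius 4–7 px, DAB OD 0.9) and
processes grown as seeded 8-connected random walks from the soma rim
(turning-angle SD 0.35 rad, branch probability 0.03/step, ≤ 2 branch
generations, 3–6 processes of 20–60 px per cell, DAB OD 0.45), then
exponentiates to 8-bit RGB and adds Gaussian intensity noise (SD 2).
Ground truth records soma centres/masks, per-cell polylines with arc
lengths (diagonal step √2 — the same metric the skeleton length uses) and
the tissue mask. An optional per-cell intensity jitter multiplies both
soma and process OD by a uniform factor. Cell density and staining
intensities are free parameters chosen to resemble 20× Iba1 fields; they
are not calibrated to any specific dataset. Scenes are not
photorealistic: no uneven illumination, no chromatic aberration, no
overlapping or out-of-focus cells, and process width is exactly one
pixel. Passing tests therefore demonstrate correctness of the
*algorithmic* chain under its stated assumptions (well-separated cells,
adequate contrast), not segmentation performance on real slides.

The MRI simulators write uniform-signal phantoms with two elliptical
white-matter-like ROIs ("cc", "ec"), per-ROI true MTR/T2, and Gaussian
(not Rician) noise — adequate for validating the quantification formulas
at the SNRs simulated, not for scanner realism. The study-table generator
produces long-format tables (study, animal, genotype, treatment,
timepoint, measure, value, units) with per-animal random intercepts for
repeated measures; default group structure is n = 7 per group over three
timepoints, matching typical cuprizone study arms.

## Numerical and design choices

* OD uses base-10 logarithm; stain matrices are rejected when the
  condition number exceeds 1e8.
* Skeleton length halves nothing twice: each link between two skeleton
  pixels is counted exactly once via directed shifts (E, S, SE, SW).
* Influence-zone ties go to the lower cell id; all pipeline stages are
  deterministic for a fixed image and config.
* `fit_standard_curve` rejects non-monotone standards outright rather
  than fitting through them.
* Simulation sizes in the test-suite and acceptance script (10–20 scenes
  per condition, 100–200 statistical replicates) were chosen as the
  smallest sizes at which the Monte-Carlo statements being checked are
  stable across seeds.

## Known limitations

Single-field 2-D images only (no whole-slide tiling, no z-stacks, no
registration); no machine-learned segmentation; touching or overlapping
somas are not split (no watershed), so crowded fields will undercount;
MTR/T2 without B0/B1 correction or multi-compartment modeling; the mixed
model supports random intercepts only, not random slopes.
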