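# Methods

## Problem and scope

`pdfftexture` quantifies the *spatial texture* of proton-density fat-fraction
(PDFF) maps from chemical shift encoding-based water–fat MRI, in segmented
compartments of the lumbar region: the erector spinae muscles (ES), the psoas
muscles (PS), and the vertebral bone marrow of L1–L4 (LS). Beyond the mean
fat fraction of a region, the package computes first-order histogram features
(how heterogeneous the voxel values are) and second-order co-occurrence
features (how that heterogeneity is arranged in space), and tests how these
features differ between groups and co-vary between compartments once age and
BMI are accounted for. Fat–water decomposition, acquisition, and manual
segmentation are out of scope: PDFF volumes and label masks are inputs.

## Preprocessing

PDFF is analyzed in percent on a fixed physical domain [0, 100]. Files
storing fractions in [0, 1] are detected (in-ROI maximum ≤ 1.5) and rescaled
×100; values outside the domain (e.g. water–fat swap artifacts) are clipped,
with counts logged. Volumes are resampled to an isotropic grid — trilinear
for intensities, nearest-neighbor for labels — with the default target equal
to the smallest input spacing, so already-isotropic data pass through
unchanged. Voxel indices are 0-based and all neighborhood logic operates in
index space; millimetres enter only through the spacing metadata.

## First-order (global) features

For each ROI, the histogram bin count is the median of three classical
rules: Sturges (⌈log₂ n⌉ + 1), Scott (width 3.49·s·n^(−1/3)) and
Freedman–Diaconis (width 2·IQR·n^(−1/3)), each converted to a count by
⌈range/width⌉ over the sample range [min, max]. A zero IQR drops the FD rule
(the median degenerates to the rounded-up mean of the remaining pair); zero
spread yields a single bin and flags the ROI. Variance(global),
Skewness(global) and Kurtosis(global) are then moments of the normalized
histogram (bin centers weighted by normalized counts); mean PDFF is computed
on the raw values. Kurtosis is reported in the *excess* convention
(normal = 0) by default — the convention cannot be pinned down from typical
reporting, so a `pearson` switch (normal = 3) is provided. Raw-value moment
versions are exposed separately (`firstorder.raw_moments`) for comparison.

## Gray-level quantization and the 3D GLCM

For second-order analysis the map is quantized into N_g = 200 equal bins
spanning the fixed 0–100 % domain (level = ⌊v/0.5⌋ + 1, 100 % assigned the
top level; half-open bins, last bin closed). The fixed domain — rather than
each ROI's own min/max — keeps gray levels comparable across subjects and
compartments.

Co-occurrence is evaluated over the 26-neighborhood at distance 1: the 13
unique displacement directions of {−1,0,1}³ modulo sign. For each direction,
every ordered voxel pair whose *both* endpoints carry the ROI label is
counted (no padding; pairs leaving the ROI or grid contribute nothing), the
count matrix is symmetrized by adding its transpose, and normalized to a
joint probability matrix. Eight features are computed per direction —
Energy, Entropy (base-2, in bits), Contrast, Homogeneity, Correlation,
Variance, Sum Average, Dissimilarity — using the standard co-occurrence
definitions (Variance is the marginal variance about the marginal mean μ_x;
Sum Average is Σ k·p_{x+y}(k), without the ×½ rescaling some toolboxes
apply). Rotation invariance comes from averaging the *features* (not the
matrices) over the 13 directions. Because axial, planar-diagonal and
space-diagonal offsets have physical lengths 1, √2 and √3 voxels, the
average weights each direction by the inverse of its offset length by
default; `direction_weighting="uniform"` selects the plain mean. Directions
with no valid pair are skipped (their weight renormalized away); an ROI with
no valid pair in any direction is an error. A constant ROI has undefined
Correlation, reported as 0 with a flag.

## Aggregation

Features are computed per ROI and then combined: left/right muscle values
are averaged with weights proportional to side volume (mm³); the four
vertebrae are averaged unweighted. The asymmetry is deliberate — muscle
sides differ systematically in volume, vertebral levels are treated as
replicates. A missing side or vertebra degrades gracefully with a warning
and a flag.

## Statistics

* **Normality screen** — one-sample Kolmogorov–Smirnov against a normal with
  the sample's own mean/SD (the routine screen of standard stats software;
  note that estimating the parameters makes it conservative).
* **Demographics** — two-sided Mann–Whitney U; exact enumeration for small
  tie-free samples, tie-corrected normal approximation otherwise.
* **Sex differences** — one logistic regression per feature per compartment:
  logit P(male) = β₀ + β₁·feature + β₂·age + β₃·BMI, maximum likelihood,
  two-sided Wald p for β₁. Predictors are z-scored internally; the Wald p is
  invariant to affine rescaling. Separation or ML divergence falls back to a
  Firth (Jeffreys-prior penalized) fit, flagged in the output. Male is coded
  1, so a positive direction means higher values in males.
* **Cross-compartment association** — partial Pearson correlation: both
  variables are residualized on [1, age, BMI] by least squares; r of the
  residuals is tested with t = r·√((n−2−k)/(1−r²)) on n−2−k df (k = 2).
* No multiple-testing correction by default (α = 0.05 per test);
  Benjamini–Hochberg is available behind `--fdr`.

The analysis bundle emits a demographics-and-features summary (per-sex
mean ± SD and the adjusted logistic p for each of the 12 features × 3
compartments), a partial-correlation table (each feature, LS vs ES and LS vs
PS), and a plain-text report. Flagged results propagate; a single-sex table
skips the logistic section with a diagnostic.

## Synthetic data

No imaging cohort is bundled; the generator produces volumes with the
*statistical* structure the analysis assumes, not anatomy.

Each ROI is filled from a stationary random field: white Gaussian noise
convolved with a Gaussian kernel (sigma = `corr_length_mm`, default 1.2 mm —
chosen so that at 200 levels the realized Contrast of muscle-like fields
sits in the few-hundreds range typical of in-vivo maps), standardized
*analytically* (population smoothing variance, not the sample's), warped to
a target skewness by the monotone gamma-quantile transform of the Gaussian
copula, scaled to the target mean/SD, and clipped to [0, 100]. Analytic
standardization matters for heavy-tailed targets: per-sample standardization
is spike-dominated and biases within-ROI variance.

Default per-sex texture targets use the reference cohort's compartment
means and SDs (SD = √Variance(global)), and each compartment mean gets an
independent per-subject offset with the reference between-subject SD — so
mean PDFF varies realistically across subjects without inducing
cross-compartment mean correlations (consistent with the near-zero PDFF
spine–muscle partial correlations reported in healthy adults). For muscle,
the implied within-ROI coefficient of variation exceeds 1, so no
[0,100]-supported distribution can be near-symmetric; muscle distributions
are therefore modeled as gamma shapes *anchored at 0 %*, re-deriving the
skewness per subject as 2·SD/mean (the minimum feasible), which is also the
physically sensible shape for muscle fat infiltration (mostly lean voxels
with a fatty tail). Vertebral marrow sits mid-range where the reference
skewness values (−0.38/−0.06) are feasible and used directly.

The phantom contains two tube-like ES ROIs and two tube-like PS ROIs of
deliberately unequal left/right volume (exercising the volume-weighted
average) and four ellipsoidal vertebrae, in a 40×40×32 grid at 1.5 mm
isotropic — a scaled-down geometry (ROIs of ~300–1600 voxels) chosen to keep
whole-cohort simulations cheap while leaving every ROI comfortably large
enough for 13-direction co-occurrence statistics.

Between-subject structure: every compartment's SD is multiplied by
1 + γ·(λ·u + √(1−λ²)·e_c), with u a subject-level latent factor, e_c
compartment noise, γ = `sd_rel_jitter` (default 0.2) and λ =
`shared_loading`. λ is the knob behind cross-compartment heterogeneity
correlations; the defaults were set by the built-in calibration sweep
(`calibrate_shared_loading`): γ large enough that the planted heterogeneity
signal dominates finite-ROI estimation noise, and λ = 0.93 so that the
realized partial correlation of Variance(global) between spine and muscle
in default 13 + 31 cohorts is ≈ 0.6, the scale reported for healthy adults.
One consequence of a latent *variance* factor is that variance-coupled
second-order features (Contrast, Dissimilarity) co-vary between compartments
as well; only the Variance(global) association is a calibrated target. Demographics are truncated
normals (age ≥ 18) with sex-specific reference moments; optional confounding
injects a linear dependence of compartment means on age (`age_slope`,
default 0).

What passing tests on these phantoms do **not** show: robustness to
anatomy-driven effects (partial-volume voxels at ROI borders, bias fields,
intermuscular fascia), to segmentation error, or to non-stationary texture —
the fields are stationary within each ROI by construction.

## Numerical choices and degenerate inputs

* Quantization edges fixed at 0 and 100; v = 100 maps to the top level.
* GLCM features on a dense N_g×N_g matrix with cached index-difference
  grids; 0·log 0 = 0 in the entropy.
* Resampling anchors voxel 0 and never extrapolates past the last source
  voxel center; output extent is preserved within one voxel.
* Residuals with SD ≤ 1e−10 of the variable's scale count as constant
  (flagged) in partial correlation.
* All randomness flows from one seed through spawned per-subject streams, so
  any subject subset is reproducible; two runs with one seed are
  byte-identical.

## Problem sizes used in the built-in checks

The oracle and invariance checks use ≤ 8³ volumes with ≤ 8 gray levels
(where exact brute-force enumeration is feasible); calibration simulations
use 500 replicates at the study's 13 + 31 group sizes; the cross-compartment
recovery check uses 100 replicate cohorts of 44 subjects with the
first-order-only extraction path (the recovered quantity, Variance(global),
is a first-order feature); the end-to-end determinism check runs the full
CLI pipeline on an 8-subject cohort.

## Known limitations

* Sum Average scaling follows the plain Σ k·p_{x+y}(k) definition; toolboxes
  that halve it will report half these values.
* The GLCM Variance variant implemented is the marginal (μ_x) form.
* The KS screen with estimated parameters is anti-conservative in no
  direction but loses power; it is a screen, not a gate.
* Realized within-ROI variance in phantoms is slightly below the field
  target because spatially correlated fields lose variance over finite ROIs;
  calibrated quantities (λ) are defined on realized, not nominal, values.
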