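# Methods

## Scope and flow

The package implements one analysis chain: (1) synthesize or load
diffusion-weighted volumes; (2) fit a diffusion tensor per voxel; (3) take
ROI means of diagonal tensor elements in single-slice projection- and
association-fiber ROIs and form the ALPS index per hemisphere, averaging two
observers where two ROI sets exist; (4) measure tumor and edema volumes from
planar polygon stacks; (5) run the cohort statistics. Every stage consumes
standard formats (NIfTI, FSL bval/bvec, JSON polygon lists, CSV cohort
tables, YAML configs) so synthetic and real inputs are interchangeable.

## Tensor model and estimator

Signals follow the mono-exponential tensor model
`S_i = S0 · exp(−b_i · g_iᵀ D g_i)` with D a symmetric 3×3 tensor in mm²/s.
Estimation is weighted log-linear least squares per voxel: the log-signal is
regressed on `[1, −b g g ᵀ]` with signal-squared weights, the standard
first-order variance stabilisation for log-transformed Gaussian noise.
After the initial observed-signal-weighted pass, one reweighting iteration
refits with weights from the predicted signals; weighting with noisy
observations couples weights to residuals and biases the fit, and the
refit removes that component while leaving noiseless data untouched (the
predicted and observed signals then coincide, so the noiseless inverse
remains exact to ~1e-15 relative). Multiple b = 0 volumes are averaged
before fitting. Closed-form weighted least squares was chosen over
nonlinear fitting: it is deterministic and at b = 1000 s/mm² the two are
practically equivalent.

Degenerate inputs: non-positive signals are floored at 1e-10 and voxels with
no positive signal at all are flagged invalid with a zero tensor; fitted
tensors with negative eigenvalues are eigen-clipped to 1e-6 mm²/s and the
voxel flagged (ROI extraction warns when such voxels contribute to a mean).
The image-coordinate convention is fixed (x right–left, y
anterior–posterior, z craniocaudal) and gradient tables are assumed already
expressed in it; a `flip` flag on the loader handles tables with opposite
sign conventions rather than guessing.

## ALPS computation

ROI means of the diagonal elements are taken first and a single index is
computed from the four means (not per-voxel indices averaged): the index is
a ratio of representative fiber diffusivities, and averaging first matches
that reading. "x-axis diffusivity" is the Dxx element in image coordinates,
not a projection onto a fitted vessel axis. ROIs are constrained to a
single axial slice, matching single-slice placement at the ventricle body.
Observer averaging happens on indices (each observer's measurement is an
index); averaging the four diffusivities first would differ only at second
order. Hemisphere attribution follows the ROI labels; a subject's
"ipsilateral" index is the index on the tumor side, and controls carry both
sides with no ipsilateral designation.

## The phantom

The phantom is a periventricular geometry only — no whole-brain anatomy, no
CSF compartment, no tumor signal. Four axis-aligned fiber slabs at fixed
fractional coordinates (association lateral to projection in each
hemisphere, right hemisphere at low x) sit in an isotropic background
(0.7e-3 mm²/s). Projection-fiber voxels carry diag(λ⊥ + boost, λ⊥, λ∥),
association-fiber voxels diag(λ⊥ + boost, λ∥, λ⊥), with defaults
λ∥ = 1.4e-3, λ⊥ = 0.4e-3 mm²/s (typical deep white matter) and
boost = 0.2e-3, giving ground-truth ALPS (λ⊥ + boost)/λ⊥ = 1.5 at the top
of the observed clinical range. The acquisition mirrors the study protocol:
one b = 0 plus 20 directions (Fibonacci-sphere layout) at b = 1000 s/mm²,
2 mm isotropic voxels, 4 signal averages. Noise is additive Gaussian with
sd S0/SNR per average — a Rician approximation that is adequate at
SNR ≥ 10 and keeps the noise model invertible for tests; SNR 0 disables
noise entirely.

The default grid is 96×96×4 voxels. The in-plane slab extent was sized from
an error budget: a single-slice ROI of ~500 voxels brings the standard
error of the ROI-mean diffusivities low enough that the recovered index at
SNR 30 with 4 averages sits within 0.01 of the closed form, the recovery
tolerance the tests assert. Real ROIs are far smaller (~29 mm²); the
phantom trades anatomical realism of ROI size for a sharp identifiability
check of the estimator chain, which is its purpose. What passing phantom
tests do *not* show: robustness to misregistration, fiber curvature or
crossing, CSF partial voluming, or Rician floor effects at low SNR — none
of which the phantom contains.

## Volumetry

Volume = Σ polygon area × slice thickness, per lesion, summed over lesions,
with no inter-slice interpolation (contiguous thin slices make the
difference negligible, and the non-interpolating convention is declared
rather than inferred). Areas are shoelace areas (via shapely), checked
against a 0.05 mm rasterization oracle in the tests. Polygons must be
simple (non-self-intersecting) with ≥ 3 finite vertices and positive area;
one lesion may contribute at most one polygon per slice. Exclusion rules
(dural tails, necrosis, calcification) belong to whoever draws the ROIs and
cannot be enforced by the measuring code. Absent edema is encoded as a
volume of exactly 0 cm³.

## Cohort simulator

Groups: meningiomas without PTBE, meningiomas with PTBE (each per tumor
side), and controls. Per-group ALPS indices are normal with the study's
printed means/SDs; demographics default to the printed values (patients age
58.8 ± 13.5 truncated to [18, 95], 37/80 men; controls 53.3 ± 10.0, 23/44
men). PTBE volume is a normal(67.1, 46.8) truncated at 0 — the study prints
only mean, SD and bin counts, so the truncated normal is a stand-in for an
unknown shape, not an inference. In PTBE+ groups the tumor-side ALPS and
the PTBE volume are linked by a Gaussian copula at Pearson rho (default
−0.68). Because pushing a normal through the truncated-normal quantile
transform attenuates the correlation, the latent normal correlation is set
to rho/λ with λ = corr(Z, g(Z)) computed by Gauss–Hermite quadrature; the
configured rho is then the actual Pearson correlation of the generated
pairs (Monte-Carlo over the generator recovers it to < 0.01). Ki-67 is
normal(4.8, 3.1) truncated to the reported range [1, 12]; tumor volume
normal(58.6, 45.3) truncated at 1 cm³; sex/grade/location are Bernoulli at
the printed proportions. All draws come from one seeded generator in a
fixed order, so identical configs give bit-identical tables.

The simulator emulates the *marginal and correlation structure* the
analysis assumes — it does not emulate within-subject coupling between the
two hemispheres' indices, site-dependent edema rates, or any mechanism
linking tumor volume to edema, so passing statistics tests shows the
estimators and tests behave correctly under the declared structure, not
that the structure is true of real cohorts.

A deterministic 80-row reference table reproduces the study's descriptive
margins exactly (sex, site, grade, volume-bin counts, side-by-edema
splits), with columns assigned independently since only margins are
published; it anchors the descriptive-report tests.

## Statistics

* **Normality gate**: Lilliefors-corrected Kolmogorov-Smirnov (moments are
  estimated from the sample). The flag is recorded; the analysis proceeds
  parametrically, as the study's variables passed the gate.
* **ICC**: single-rater absolute-agreement two-way random-effects ICC(A,1)
  computed from the ANOVA mean squares, with the McGraw–Wong F-based 95% CI
  (Satterthwaite df) and p from F = MSR/MSE. Zero between-subject variance
  is flagged undefined rather than reported as a number. Tests cross-check
  against pingouin and a from-scratch ANOVA oracle. Minimum 3 subjects
  (needed for the CI df).
* **ANCOVA**: one OLS fit `response ~ group + age + sex` per side and
  response; pairwise contrasts are differences of covariate-adjusted group
  means using the pooled residual variance (estimated-marginal-means
  style), not per-pair t-tests. Bonferroni: each raw p × 3 (the three
  pairwise comparisons of one model — families are not pooled across the
  four side/response combinations), capped at 1, with CIs widened to joint
  95% coverage. Right- and left-side cohorts are compared with controls
  separately because the index has no reference range and differs between
  hemispheres.
* **Correlations**: Pearson r with the t-based two-sided p; dichotomies
  (sex man=0/woman=1, grade I=0/II-III=1, location non-skull-base=0/
  skull-base=1) enter on their 0/1 coding, i.e. point-biserial.
* **VIF**: 1/(1 − R²) from regressing each candidate on the others with
  intercept; exact collinearity reports inf.
* **Stepwise regression**: forward entry at p ≤ 0.05 and backward removal
  at p ≥ 0.10 on partial F tests (the common defaults of the study's
  software, which names the procedure but not its thresholds). Ties break
  on smaller entry p, then fixed candidate order. Selection stops when the
  fit is numerically perfect (residual SS ≤ 1e-12 of total), where further
  partial F tests are 0/0 noise. If nothing enters, the intercept-only
  model is returned — a result, not an error. Standardized β =
  b·sd(x)/sd(y) of the final model; the step-by-step trace is part of the
  result. Under seven null candidates the per-candidate entry rate is ≈ 5%,
  so the family-wise false-entry rate is ≈ 1 − 0.95⁷ ≈ 30%; with one strong
  true predictor the true one is selected essentially always, and the modal
  outcome is the true predictor alone.

## Problem sizes and tolerances

Simulation-based checks use 1000 replicates (Monte-Carlo tolerances in the
tests assume that count): cohort ANCOVA replicates at n = 88, stepwise
power/null replicates at n = 56 with 7 candidates, correlation recovery at
n = 56. Phantom recovery tests run one noiseless phantom and a four-point
boost grid at SNR 30 on the default 96×96×4 grid. Exact identities
(noiseless tensor inversion, shoelace vs rasterization, ICC/VIF oracles)
are asserted at 1e-12 or the stated oracle resolution.

## Known limitations

* The phantom's fibers are axis-aligned homogeneous slabs; no curvature,
  crossing, partial voluming or anatomy, and ROI placement is deterministic
  rather than observer-driven.
* Gaussian noise stands in for Rician; below SNR ~10 the approximation
  (and the log-linear estimator) degrade together.
* The simulated PTBE marginal and the Ki-67/tumor-volume truncation ranges
  are stand-ins constrained only by printed summary statistics.
* No nonparametric fallback branch exists (the normality gate is recorded,
  not acted on), and there is no missing-data machinery: cohort rows with
  NaNs in model variables are dropped by the model-fitting steps.
* Patient-level results of the original cohort are not reproducible from
  summary parameters; group-level patterns (contrast significance
  structure, correlation magnitude, sole stepwise selection) are the
  reproducible targets.
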